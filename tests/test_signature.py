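"""Two-stage bootstrap elastic-net signature selection."""

import numpy as np
import pandas as pd
import pytest

from kitox.signature import (
    RegressionDataset,
    SignatureModel,
    bootstrap_selection,
    drug_exclusion_sensitivity,
    elastic_net_fit,
    fit_signature,
    importance_cutoff,
    percentile_sweep,
    predict_risk,
    run_signature_pipeline,
    split_holdout,
)


def _dataset(rng, n=23, p=40, signal=("g000",), beta=2.0, noise=0.05):
    genes = [f"g{i:03d}" for i in range(p)]
    drugs = [f"D{i:02d}" for i in range(n)]
    X = pd.DataFrame(rng.normal(size=(n, p)), index=drugs, columns=genes)
    y = pd.Series(noise * rng.normal(size=n), index=drugs)
    for g in signal:
        y = y + beta * X[g]
    return RegressionDataset(X, y)


class TestSplitHoldout:
    def test_disjoint_exhaustive(self, rng):
        ds = _dataset(rng)
        train, test = split_holdout(ds, n_test=2, seed=1)
        assert len(train.drugs) == 21 and len(test.drugs) == 2
        assert set(train.drugs) | set(test.drugs) == set(ds.drugs)
        assert not set(train.drugs) & set(test.drugs)

    def test_seed_deterministic(self, rng):
        ds = _dataset(rng)
        a = split_holdout(ds, seed=7)[1].drugs
        b = split_holdout(ds, seed=7)[1].drugs
        assert list(a) == list(b)

    def test_zero_test_drugs(self, rng):
        ds = _dataset(rng)
        train, test = split_holdout(ds, n_test=0, seed=1)
        assert len(test.drugs) == 0 and len(train.drugs) == len(ds.drugs)

    def test_too_many_rejected(self, rng):
        with pytest.raises(ValueError):
            split_holdout(_dataset(rng, n=5), n_test=5)


class TestElasticNetFit:
    def test_unpenalised_equals_ols(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        y = pd.Series(2 * X["a"].to_numpy() + rng.normal(size=10) * 0.1)
        fit = elastic_net_fit(X, y, alpha=0.5, lam=0.0)
        A = np.column_stack([np.ones(10), X.to_numpy()])
        beta = np.linalg.lstsq(A, y.to_numpy(), rcond=None)[0]
        assert np.allclose(fit.coef.to_numpy(), beta[1:], atol=1e-8)
        assert np.allclose(fit.predict(X), A @ beta, atol=1e-8)

    def test_full_shrinkage_limit(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 4)))
        y = pd.Series(rng.normal(size=12))
        fit = elastic_net_fit(X, y, alpha=0.5, lam=1e6)
        assert np.allclose(fit.coef_std.to_numpy(), 0.0)
        assert fit.intercept == pytest.approx(y.mean())

    def test_ridge_matches_closed_form(self, rng):
        X = pd.DataFrame(rng.normal(size=(15, 5)))
        y = pd.Series(rng.normal(size=15))
        lam = 0.37
        fit = elastic_net_fit(X, y, alpha=0.0, lam=lam)
        Xs = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        yc = y.to_numpy() - y.mean()
        w = np.linalg.solve(Xs.T @ Xs + 15 * lam * np.eye(5), Xs.T @ yc)
        assert np.allclose(fit.coef_std.to_numpy(), w, atol=1e-8)

    def test_univariate_lasso_soft_threshold(self, rng):
        x = rng.normal(size=20)
        y_raw = 1.5 * x + rng.normal(size=20) * 0.2
        X = pd.DataFrame({"a": x})
        y = pd.Series(y_raw)
        lam = 0.3
        fit = elastic_net_fit(X, y, alpha=1.0, lam=lam)
        xs = (x - x.mean()) / x.std()
        yc = y_raw - y_raw.mean()
        rho = (xs @ yc) / 20
        expected = np.sign(rho) * max(abs(rho) - lam, 0.0)
        assert fit.coef_std.iloc[0] == pytest.approx(expected, abs=1e-8)

    def test_invalid_parameters_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 2)))
        y = pd.Series(rng.normal(size=5))
        with pytest.raises(ValueError):
            elastic_net_fit(X, y, alpha=1.5, lam=0.1)
        with pytest.raises(ValueError):
            elastic_net_fit(X, y, alpha=0.5, lam=-0.1)

    def test_zero_variance_column_dropped(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=8), "b": np.ones(8)})
        y = pd.Series(rng.normal(size=8))
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = elastic_net_fit(X, y, alpha=0.5, lam=0.1)
        assert list(fit.coef.index) == ["a"]


class TestBootstrapSelection:
    def test_noiseless_signal_selected(self, rng):
        # many null genes so each fit can only touch a small fraction of them
        ds = _dataset(rng, n=20, p=500, signal=("g000",), noise=0.0)
        summary = bootstrap_selection(ds, B=25, seed=3)
        assert summary.selection_frequency["g000"] >= 0.95
        null_phi = summary.selection_frequency.drop("g000")
        assert null_phi.median() == pytest.approx(0.0, abs=0.05)

    def test_single_bootstrap_binary_frequencies(self, rng):
        ds = _dataset(rng, n=15, p=20)
        summary = bootstrap_selection(ds, B=1, seed=0)
        assert set(summary.selection_frequency.unique()) <= {0.0, 1.0}

    def test_never_selected_gene_has_zero_importance(self, rng):
        ds = _dataset(rng, n=15, p=30)
        summary = bootstrap_selection(ds, B=10, seed=0)
        never = summary.selection_frequency == 0
        assert (summary.importance[never] == 0).all()
        # and I = 0 only for never-selected genes
        assert (summary.importance[~never] > 0).all()

    def test_invariant_to_row_and_column_order(self, rng):
        ds = _dataset(rng, n=12, p=15)
        shuffled = RegressionDataset(
            ds.X.iloc[::-1, ::-1], ds.y.iloc[::-1]
        )
        a = bootstrap_selection(ds, B=5, seed=9)
        b = bootstrap_selection(shuffled, B=5, seed=9)
        pd.testing.assert_series_equal(a.importance, b.importance)

    def test_scaled_coefficients_bounded(self, rng):
        ds = _dataset(rng, n=15, p=25)
        summary = bootstrap_selection(ds, B=10, seed=4)
        assert (summary.mean_scaled_coefficient >= 0).all()
        assert (summary.mean_scaled_coefficient <= 1 + 1e-12).all()


class TestPercentileSweep:
    def test_printed_signature_size_convention(self, rng):
        # 10,749 distinct importances, 99.755th percentile, strict-above
        values = pd.Series(
            rng.permutation(np.linspace(0.001, 1.0, 10_749)),
            index=[f"g{i:05d}" for i in range(10_749)],
        )
        assert len(importance_cutoff(values, 99.755)) == 26

    def test_zero_percentile_keeps_everything(self, rng):
        values = pd.Series(rng.random(50))
        assert len(importance_cutoff(values, 0.0)) == 50

    def test_dominant_gene_beats_intercept_only(self, rng):
        ds = _dataset(rng, n=18, p=12, signal=("g000",), noise=0.02)
        summary = bootstrap_selection(ds, B=20, seed=5)
        q_star, subset, curve = percentile_sweep(
            summary, ds, percentile_grid=[50.0, 90.0, 99.0], seed=6
        )
        assert "g000" in set(subset)
        y = ds.y.to_numpy()
        n = len(y)
        loo_int = np.sqrt(
            np.mean([(y[i] - np.delete(y, i).mean()) ** 2 for i in range(n)])
        )
        assert curve["loo_rmse"].min() < loo_int

    def test_tie_breaks_to_sparser_percentile(self, rng):
        ds = _dataset(rng, n=10, p=6)
        summary = bootstrap_selection(ds, B=5, seed=1)
        # a grid with duplicate entries forces at least one exact RMSE tie
        q_star, _, curve = percentile_sweep(
            summary, ds, percentile_grid=[90.0, 90.0], seed=2
        )
        assert q_star == 90.0


class TestSignatureModel:
    def test_single_perfect_predictor_recovered(self, rng):
        ds = _dataset(rng, n=20, p=5, signal=("g001",), beta=3.0, noise=0.0)
        model = fit_signature(ds, ["g001"], lambda_rule=1e-8)
        report = predict_risk(model, ds.X, observed=ds.y)
        assert report.rmse == pytest.approx(0.0, abs=1e-6)

    def test_variable_importance_max_is_one(self, rng):
        ds = _dataset(rng, n=20, p=10, signal=("g000", "g001"))
        model = fit_signature(ds, ["g000", "g001", "g002"], lambda_rule=0.01)
        assert max(model.variable_importance.values()) == pytest.approx(1.0)

    def test_prediction_reproducible_from_stored_parameters(self, rng):
        ds = _dataset(rng, n=15, p=8)
        model = fit_signature(ds, list(ds.genes[:4]), lambda_rule=0.05)
        rebuilt = SignatureModel.from_json(model.to_json())
        row = ds.X.iloc[0]
        assert rebuilt.predict(row) == pytest.approx(model.predict(row), abs=1e-12)

    def test_all_zero_profile_gives_standardisation_offset(self, rng):
        ds = _dataset(rng, n=15, p=4)
        model = fit_signature(ds, list(ds.genes), lambda_rule=0.05)
        zero = pd.Series(0.0, index=ds.genes)
        expected = model.intercept + sum(
            model.coef_std[g] * (0 - model.mean[g]) / model.sd[g] for g in model.genes
        )
        assert model.predict(zero) == pytest.approx(expected, abs=1e-12)

    def test_missing_gene_error_lists_genes(self, rng):
        ds = _dataset(rng, n=15, p=4)
        model = fit_signature(ds, list(ds.genes), lambda_rule=0.05)
        with pytest.raises(KeyError, match="g000"):
            model.predict(pd.Series({"g001": 1.0}))

    def test_subset_gene_absent_rejected(self, rng):
        ds = _dataset(rng, n=10, p=4)
        with pytest.raises(KeyError):
            fit_signature(ds, ["nope"], lambda_rule=0.05)


class TestDrugExclusion:
    def test_table_complete_and_duplicate_drug_inert(self, rng):
        ds = _dataset(rng, n=10, p=8, signal=("g000",), noise=0.02)
        # duplicate one drug's row under a new id: excluding the copy ~ no-op
        X = pd.concat([ds.X, ds.X.iloc[[0]].set_index(pd.Index(["Ddup"]))])
        y = pd.concat([ds.y, pd.Series({"Ddup": ds.y.iloc[0]})])
        dup = RegressionDataset(X, y)
        summary = bootstrap_selection(dup, B=10, seed=2)
        table = drug_exclusion_sensitivity(
            dup, summary, percentile_grid=[80.0], seed=3
        )
        assert len(table) == len(dup.drugs)
        delta_dup = float(
            table.set_index("excluded_drug").loc["Ddup", "delta_rmse"]
        )
        assert abs(delta_dup) < 0.05 * max(1.0, ds.y.abs().max())

    def test_leverage_drug_matters_more_than_noise_drug(self, rng):
        # one drug anchors the low-risk extreme; a pure-noise drug does not
        ds = _dataset(rng, n=12, p=6, signal=("g000",), noise=0.02)
        X = ds.X.copy()
        y = ds.y.copy()
        X.loc["Dlow"] = 0.0
        X.loc["Dlow", "g000"] = -6.0
        y["Dlow"] = -12.0
        lev = RegressionDataset(X.sort_index(), y.sort_index())
        summary = bootstrap_selection(lev, B=10, seed=4)
        table = drug_exclusion_sensitivity(
            lev, summary, percentile_grid=[80.0], seed=5
        ).set_index("excluded_drug")
        others = table.drop("Dlow")["delta_rmse"].abs().median()
        assert abs(table.loc["Dlow", "delta_rmse"]) >= others


class TestEndToEnd:
    def test_pipeline_bit_reproducible(self, rng):
        ds = _dataset(rng, n=14, p=20, signal=("g000",), noise=0.05)
        kw = dict(n_test=2, B=8, percentile_grid=[80.0, 95.0], seed=123)
        a = run_signature_pipeline(ds, **kw)
        b = run_signature_pipeline(ds, **kw)
        assert a["model"].to_json() == b["model"].to_json()
        pd.testing.assert_frame_equal(a["rmse_curve"], b["rmse_curve"])
        pd.testing.assert_frame_equal(a["validation"].table, b["validation"].table)

    def test_recovery_improves_with_less_noise(self):
        # statistically: lower noise recovers at least as many signal genes
        from kitox import synthetic

        recovered = {}
        for noise in (8.0, 0.1):
            cfg = synthetic.SyntheticStudyConfig(
                n_genes=200, n_drugs=23, noise_sd=noise, seed=77
            )
            study = synthetic.generate_expression_study(cfg)
            ds = synthetic.study_regression_dataset(study)
            res = run_signature_pipeline(
                ds, n_test=2, B=25, percentile_grid=[90.0, 95.0, 99.0], seed=9
            )
            recovered[noise] = len(
                set(res["model"].genes) & set(study.signal_genes)
            )
        assert recovered[0.1] >= recovered[8.0]
        assert recovered[0.1] >= 8
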