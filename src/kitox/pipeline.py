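"""End-to-end orchestration: validated config in, stage outputs + manifest out.

A single YAML config with per-stage sections drives risk scoring ->
profiling -> enrichment -> signature regression -> chemistry. Every stage
writes fixed-name TSV/JSON outputs under the run directory, and the manifest
records the config snapshot, package version, per-file checksums and
timestamps, so identical config + inputs reproduce identical checksums for
the deterministic stages. One top-level seed is expanded into named
per-stage substreams.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, chem, enrichment, expression, faers, io, signature, synthetic

__all__ = ["RunConfig", "ValidationIssue", "validate_inputs", "run_pipeline"]

_STAGES = ("simulate", "risk", "profiles", "enrich", "signature", "chem")


@dataclass
class RunConfig:
    """Parsed pipeline configuration (one optional section per stage)."""

    seed: int
    output_dir: Path
    stages: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        problems = []
        if "output_dir" not in raw:
            problems.append("output_dir")
        if "seed" not in raw:
            problems.append("seed")
        unknown = set(raw) - set(_STAGES) - {"seed", "output_dir"}
        if unknown:
            problems.append(f"unknown sections: {sorted(unknown)}")
        if problems:
            raise ValueError(f"invalid config, offending fields: {problems}")
        stages = {s: raw[s] or {} for s in _STAGES if s in raw}
        return cls(int(raw["seed"]), base / raw["output_dir"], stages)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass(frozen=True)
class ValidationIssue:
    stage: str
    message: str
    fatal: bool


def validate_inputs(config: RunConfig) -> list[ValidationIssue]:
    """Schema and cross-table consistency checks (fatal vs warning)."""
    issues: list[ValidationIssue] = []
    s = config.stages

    def path_of(stage: str, key: str) -> Path | None:
        v = s.get(stage, {}).get(key)
        return Path(v) if v else None

    for stage, key in (
        ("risk", "report_table"),
        ("risk", "event_group"),
        ("enrich", "gmt"),
        ("chem", "fingerprints"),
        ("chem", "kd_matrix"),
    ):
        p = path_of(stage, key)
        if stage in s and "simulate" not in s and p is None:
            issues.append(ValidationIssue(stage, f"missing required input '{key}'", True))
        elif p is not None and not p.exists():
            issues.append(ValidationIssue(stage, f"unreadable file: {p}", True))

    if "profiles" in s and "simulate" not in s:
        tables = s["profiles"].get("fold_change_tables") or []
        if not tables:
            issues.append(
                ValidationIssue("profiles", "missing required input 'fold_change_tables'", True)
            )
        for t in tables:
            if not Path(t).exists():
                issues.append(ValidationIssue("profiles", f"unreadable file: {t}", True))

    # drug-id joins, when both sides are readable
    try:
        rt = path_of("risk", "report_table")
        tables = s.get("profiles", {}).get("fold_change_tables") or []
        if rt and rt.exists() and tables and all(Path(t).exists() for t in tables):
            report = io.read_report_table(rt)
            expr_drugs: set[str] = set()
            for t in tables:
                expr_drugs |= set(io.read_fold_change_table(t).log_fc.columns)
            only_risk = set(report.drugs) - expr_drugs - {synthetic.COMPARATOR_ID}
            if only_risk and "signature" in s:
                issues.append(
                    ValidationIssue(
                        "signature",
                        f"drugs in report table absent from expression: {sorted(only_risk)}",
                        True,
                    )
                )
    except Exception as exc:  # unreadable/garbled inputs are fatal
        issues.append(ValidationIssue("validate", f"failed to cross-check inputs: {exc}", True))
    return issues


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict.

    Stage failures abort with the failing stage named. Outputs land under
    ``output_dir`` with fixed names; the manifest is written as
    ``manifest.json``.
    """
    fatal = [i for i in validate_inputs(config) if i.fatal]
    if fatal:
        raise ValueError("; ".join(f"[{i.stage}] {i.message}" for i in fatal))

    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    s = config.stages
    study = None

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    try:
        if "simulate" in s:
            params = dict(s["simulate"])
            params.setdefault("seed", config.stage_seed("simulate"))
            cfg = synthetic.SyntheticStudyConfig(**params)
            study = synthetic.generate_study(cfg)
            io.write_report_table(study.report_table, emit(out / "report_table.tsv"))
            for cl, table in study.expression.items():
                io.write_fold_change_table(table, emit(out / f"fold_change_{cl}.tsv"))
            io.write_fingerprints(study.fingerprints, emit(out / "fingerprints.tsv"))
            io.write_matrix(study.kd_matrix, emit(out / "kd_matrix.tsv"), "drug")
            io.write_matrix(
                study.true_risk.to_frame(), emit(out / "true_risk.tsv"), "drug"
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    risk_scores: pd.Series | None = None
    try:
        if "risk" in s or study is not None:
            rs = s.get("risk", {})
            if study is not None and "report_table" not in rs:
                table = study.report_table
                group = synthetic.TARGET_EVENT_GROUP
            else:
                table = io.read_report_table(rs["report_table"])
                group = io.read_event_group(rs["event_group"])
            scores = faers.score_table(
                table, group, zero_correction=bool(rs.get("zero_correction", False))
            )
            scores = [sc for sc in scores if sc.drug != synthetic.COMPARATOR_ID]
            io.write_risk_scores(scores, emit(out / "risk_scores.tsv"))
            risk_scores = pd.Series({sc.drug: sc.risk_score for sc in scores})
    except Exception as exc:
        raise RuntimeError(f"stage 'risk' failed: {exc}") from exc

    profiles = None
    try:
        if "profiles" in s or study is not None:
            ps = s.get("profiles", {})
            if study is not None and not ps.get("fold_change_tables"):
                tables = list(study.expression.values())
            else:
                tables = [
                    io.read_fold_change_table(p) for p in ps["fold_change_tables"]
                ]
            drugs = sorted(set().union(*(t.log_fc.columns for t in tables)))
            profiles = [expression.median_profile(tables, d) for d in drugs]
            X = pd.DataFrame({p.drug: p.median_log_fc for p in profiles}).T
            io.write_matrix(X, emit(out / "median_profiles.tsv"), "drug")
            top_n = int(ps.get("top_n", 250))
            criterion = ps.get("criterion", "p_value")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lists = [expression.rank_genes(p, top_n, criterion) for p in profiles]
            io.write_matrix(
                expression.jaccard_matrix(lists), emit(out / "jaccard.tsv"), "drug"
            )
            with open(emit(out / "top_genes.tsv"), "w") as fh:
                for rl in lists:
                    for g in rl.genes:
                        fh.write(f"{rl.drug}\t{g}\n")
    except Exception as exc:
        raise RuntimeError(f"stage 'profiles' failed: {exc}") from exc

    try:
        if "enrich" in s and profiles is not None and risk_scores is not None:
            es = s["enrich"]
            universe = set(profiles[0].genes)
            library = io.read_gmt(es["gmt"], universe=universe)
            if es.get("blocklist"):
                library = library.without_terms(set(es["blocklist"]))
            top_n = int(es.get("top_n", 250))
            queries = {
                p.drug: expression.rank_genes(p, top_n, "p_value").as_set()
                for p in profiles
            }
            pmat = enrichment.enrichment_table(queries, library)
            io.write_matrix(pmat, emit(out / "enrichment_p.tsv"), "drug")
            corr = enrichment.correlate_terms_with_risk(
                pmat,
                risk_scores,
                p_filter=float(es.get("p_filter", 0.05)),
                r_filter=float(es.get("r_filter", 0.25)),
            )
            pd.DataFrame(
                [(c.term, c.r, c.min_p, c.passes_filters) for c in corr],
                columns=["term", "r", "min_p", "passes_filters"],
            ).to_csv(emit(out / "term_risk_correlation.tsv"), sep="\t", index=False,
                     float_format=io.FLOAT_FMT)
    except Exception as exc:
        raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc

    try:
        if "signature" in s and profiles is not None and risk_scores is not None:
            gs = s["signature"]
            X = pd.DataFrame({p.drug: p.median_log_fc for p in profiles}).T
            common = X.index.intersection(risk_scores.index)
            ds = signature.RegressionDataset(X.loc[common], risk_scores.loc[common])
            result = signature.run_signature_pipeline(
                ds,
                n_test=int(gs.get("n_test", 2)),
                B=int(gs.get("bootstraps", 1000)),
                alpha=float(gs.get("alpha", 0.5)),
                lambda_rule=gs.get("lambda_rule", "cv"),
                percentile_grid=gs.get("percentile_grid"),
                seed=config.stage_seed("signature"),
            )
            (out / "signature_model.json").write_text(result["model"].to_json())
            emit(out / "signature_model.json")
            io.write_matrix(
                pd.DataFrame(
                    {
                        "selection_frequency": result["summary"].selection_frequency,
                        "mean_scaled_coefficient": result["summary"].mean_scaled_coefficient,
                        "importance": result["summary"].importance,
                    }
                ),
                emit(out / "bootstrap_summary.tsv"),
                "gene",
            )
            result["rmse_curve"].to_csv(
                emit(out / "rmse_curve.tsv"), sep="\t", index=False,
                float_format=io.FLOAT_FMT,
            )
            if result["validation"] is not None:
                io.write_matrix(
                    result["validation"].table, emit(out / "validation.tsv"), "drug"
                )
    except Exception as exc:
        raise RuntimeError(f"stage 'signature' failed: {exc}") from exc

    try:
        if "chem" in s and risk_scores is not None:
            cs = s["chem"]
            if study is not None and "fingerprints" not in cs:
                fps = study.fingerprints
                kd = study.kd_matrix
            else:
                fps = io.read_fingerprints(cs["fingerprints"])
                kd = io.read_kd_matrix(cs["kd_matrix"])
            risks = risk_scores.to_dict()
            fps = [f for f in fps if f.molecule in risks]
            sas = chem.build_sas_map(
                fps,
                risks,
                sim_rule=cs.get("sim_rule", "percentile_90"),
                dcs_rule=cs.get("dcs_rule", "half_max"),
            )
            sas.pairs.to_csv(
                emit(out / "sas_map.tsv"), sep="\t", index=False, float_format=io.FLOAT_FMT
            )
            sel = {
                str(d): chem.selectivity_score(
                    chem.KdProfile(str(d), kd.loc[d]),
                    float(cs.get("kd_threshold", 500.0)),
                )[0]
                for d in kd.index
                if str(d) in risks
            }
            io.write_matrix(
                pd.Series(sel, name="selectivity").to_frame(),
                emit(out / "selectivity.tsv"),
                "drug",
            )
            ids = sorted(f.molecule for f in fps)
            by_id = {f.molecule: f for f in fps}
            tc = pd.DataFrame(1.0, index=ids, columns=ids)
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    v = chem.weighted_tanimoto(by_id[a], by_id[b])
                    tc.loc[a, b] = tc.loc[b, a] = v
            leaves, Z = chem.cluster_by_chemical_similarity(tc)
            (out / "chem_tree.nwk").write_text(chem.linkage_to_newick(Z, ids) + "\n")
            emit(out / "chem_tree.nwk")
            r, p = chem.promiscuity_risk_correlation(sel, risks)
            (out / "promiscuity_risk.json").write_text(
                json.dumps({"pearson_r": r, "p_value": p, "leaf_order": leaves}, indent=2)
            )
            emit(out / "promiscuity_risk.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'chem' failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in s.items()},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": {str(p.relative_to(out)): _checksum(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
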