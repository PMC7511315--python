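"""Seeded synthetic studies with the statistical structure the analysis assumes.

The generator emulates every input the pipeline consumes, with known ground
truth so estimators can be checked for recovery and consistency:

* per-cell-line differential-expression tables in which a small set of
  signal genes responds linearly to a per-drug risk score (replicate-level
  log fold-change ``beta_g * r_d + Normal(0, noise_sd)``), all other genes
  being pure noise, with p-values from a replicate-level one-sample t-test;
* adverse-event report counts drawn so the reporting odds ratio of each
  drug against a fixed background comparator pool converges to a configured
  target;
* gene-set libraries with optionally planted signal-gene sets;
* fingerprint sets derived from cluster prototypes by bit mutation, and a
  kinase Kd matrix whose binding promiscuity correlates with the risk truth
  at a configured coefficient.

All randomness flows through substreams keyed by (seed, stream, entity), so
enlarging one axis (e.g. adding genes) does not perturb draws on another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GeneSetLibrary
from .expression import FoldChangeTable, median_profile
from .faers import AdverseEventReportTable, EventGroupDefinition
from .chem import CHANNELS, FingerprintSet
from .signature import RegressionDataset

__all__ = [
    "SyntheticStudyConfig",
    "SyntheticStudy",
    "TARGET_EVENT_GROUP",
    "generate_expression_study",
    "generate_faers_counts",
    "estimated_log_rors",
    "generate_geneset_library",
    "generate_chem_assets",
    "generate_study",
    "study_regression_dataset",
]

# named RNG substreams
_S_RISK, _S_EXPR, _S_FAERS, _S_SETS, _S_CHEM = 1, 2, 3, 4, 5

#: Event terms the synthetic report tables use.
TARGET_TERMS = ("cardiac_failure", "cardiomyopathy")
OTHER_TERMS = ("rash", "nausea", "headache", "fatigue")
COMPARATOR_ID = "OTHER_KI_POOL"

#: The target adverse-event grouping for the synthetic terms.
TARGET_EVENT_GROUP = EventGroupDefinition(
    "cardiotoxicity", included=frozenset(TARGET_TERMS)
)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the analysed study's shape at a desk-scale gene count:
    23 drugs profiled in 4 cardiomyocyte cell lines, a sparse 10-gene linear
    risk signal among 2,000 genes, and a 242-kinase binding panel.
    """

    n_genes: int = 2000
    n_drugs: int = 23
    n_cell_lines: int = 4
    n_replicates: int = 6
    n_signal_genes: int = 10
    effect_sizes: tuple[float, ...] | None = None  # default: |beta| in [1, 2], alternating sign
    noise_sd: float = 0.5
    risk_range: tuple[float, float] = (-1.0, 2.0)
    reports_per_drug: int = 5000
    background_event_odds: float = 0.1
    comparator_reports: int = 1_000_000
    fingerprint_length: int = 256
    n_kinases: int = 242
    n_fp_clusters: int = 4
    fp_mutation_rate: float = 0.1
    promiscuity_risk_r: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes cannot exceed n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_event_odds <= 0:
            raise ValueError("background_event_odds must be positive")
        if self.fingerprint_length < 8:
            raise ValueError("fingerprint_length must be >= 8")
        if self.effect_sizes is not None and len(self.effect_sizes) != self.n_signal_genes:
            raise ValueError("effect_sizes must have one slope per signal gene")
        if not -1.0 <= self.promiscuity_risk_r <= 1.0:
            raise ValueError("promiscuity_risk_r must lie in [-1, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    @property
    def drug_ids(self) -> list[str]:
        return [f"D{i:02d}" for i in range(self.n_drugs)]

    @property
    def betas(self) -> np.ndarray:
        if self.effect_sizes is not None:
            return np.asarray(self.effect_sizes, dtype=float)
        mags = np.linspace(1.0, 2.0, self.n_signal_genes) if self.n_signal_genes > 1 else np.array([1.5])
        signs = np.where(np.arange(self.n_signal_genes) % 2 == 0, 1.0, -1.0)
        return mags * signs


@dataclass(frozen=True)
class SyntheticStudy:
    """All synthetic inputs plus their generating truths."""

    config: SyntheticStudyConfig
    expression: dict[str, FoldChangeTable]
    true_risk: pd.Series  # the r_d driving the signal genes
    signal_genes: tuple[str, ...]
    true_betas: pd.Series
    report_table: AdverseEventReportTable | None = None
    true_rors: pd.Series | None = None
    fingerprints: list[FingerprintSet] = field(default_factory=list)
    kd_matrix: pd.DataFrame | None = None


def _rng(seed: int, stream: int, entity: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, stream, entity])


def draw_true_risk(config: SyntheticStudyConfig) -> pd.Series:
    lo, hi = config.risk_range
    vals = [
        float(_rng(config.seed, _S_RISK, i).uniform(lo, hi))
        for i in range(config.n_drugs)
    ]
    return pd.Series(vals, index=config.drug_ids, name="risk")


def generate_expression_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Per-cell-line log-FC + p-value tables with a sparse linear risk signal.

    For signal gene g and drug d every replicate draws
    ``beta_g * r_d + Normal(0, noise_sd)``; the cell-line table entry is the
    replicate mean and the p-value a two-sided one-sample t-test of the
    replicates against zero (so p-rankings and FC-rankings correlate as in
    real differential-expression output). Null genes are pure noise.
    """
    risk = draw_true_risk(config)
    r = risk.to_numpy()
    genes = config.gene_ids
    sig_idx = np.sort(
        _rng(config.seed, _S_EXPR, 0).choice(config.n_genes, config.n_signal_genes, replace=False)
    )
    signal = {int(i): b for i, b in zip(sig_idx, config.betas)}

    L, D, R = config.n_cell_lines, config.n_drugs, config.n_replicates
    fc = np.empty((config.n_genes, L, D))
    pv = np.empty((config.n_genes, L, D))
    for gi in range(config.n_genes):
        # substream keyed by gene id: adding genes never perturbs other draws
        g_rng = _rng(config.seed, _S_EXPR, gi + 1)
        reps = g_rng.normal(0.0, 1.0, size=(L, D, R)) * config.noise_sd
        if gi in signal:
            reps += signal[gi] * r[None, :, None]
        mean = reps.mean(axis=2)
        sd = reps.std(axis=2, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(R))
        p = 2.0 * stats.t.sf(np.abs(t), df=R - 1)
        # degenerate zero-variance replicates (noiseless limit)
        p = np.where(sd == 0.0, np.where(mean == 0.0, 1.0, 0.0), p)
        fc[gi] = mean
        pv[gi] = p

    expression = {}
    for li in range(L):
        cl = f"CL{li + 1}"
        expression[cl] = FoldChangeTable(
            cl,
            pd.DataFrame(fc[:, li, :], index=genes, columns=config.drug_ids),
            pd.DataFrame(pv[:, li, :], index=genes, columns=config.drug_ids),
        )
    return SyntheticStudy(
        config=config,
        expression=expression,
        true_risk=risk,
        signal_genes=tuple(genes[i] for i in sig_idx),
        true_betas=pd.Series(config.betas, index=[genes[i] for i in sig_idx]),
    )


def generate_faers_counts(
    true_rors: pd.Series, config: SyntheticStudyConfig
) -> AdverseEventReportTable:
    """Report counts whose per-drug ROR against the comparator pool is consistent.

    Each drug files ``reports_per_drug`` reports; the target-event count is
    binomial with odds ``true_ror * background_event_odds``. A deterministic
    comparator pseudo-drug (``OTHER_KI_POOL``) carries ``comparator_reports``
    reports at exactly the background odds, fixing the reference class.
    """
    if (true_rors <= 0).any():
        raise ValueError("all target RORs must be positive")
    if config.reports_per_drug < 1:
        raise ValueError("reports_per_drug must be >= 1")
    rows = []
    for di, (drug, ror) in enumerate(true_rors.items()):
        rng = _rng(config.seed, _S_FAERS, di + 1)
        odds = float(ror) * config.background_event_odds
        p = odds / (1.0 + odds)
        f_dt = int(rng.binomial(config.reports_per_drug, p))
        f_dn = config.reports_per_drug - f_dt
        for term, cnt in zip(TARGET_TERMS, rng.multinomial(f_dt, [1 / len(TARGET_TERMS)] * len(TARGET_TERMS))):
            rows.append((drug, term, int(cnt)))
        for term, cnt in zip(OTHER_TERMS, rng.multinomial(f_dn, [1 / len(OTHER_TERMS)] * len(OTHER_TERMS))):
            rows.append((drug, term, int(cnt)))
    # deterministic background pool at exactly the background odds
    p_bg = config.background_event_odds / (1.0 + config.background_event_odds)
    f_nt = int(round(config.comparator_reports * p_bg))
    f_nn = config.comparator_reports - f_nt
    for terms, total in ((TARGET_TERMS, f_nt), (OTHER_TERMS, f_nn)):
        base, extra = divmod(total, len(terms))
        for k, term in enumerate(terms):
            rows.append((COMPARATOR_ID, term, base + (1 if k < extra else 0)))
    return AdverseEventReportTable(pd.DataFrame(rows, columns=["drug", "event_term", "count"]))


def estimated_log_rors(
    table: AdverseEventReportTable, drugs: list[str]
) -> pd.Series:
    """Per-drug log ROR estimated against the fixed comparator pool only.

    Restricting the table to (drug, pool) pairs makes the reference class the
    background pool the generator fixed, so the estimator is consistent for
    the configured target ROR.
    """
    from .faers import build_contingency, compute_ror

    out = {}
    for drug in drugs:
        sub = table.subset([drug, COMPARATOR_ID])
        ct = build_contingency(sub, drug, TARGET_EVENT_GROUP)
        out[drug] = compute_ror(ct, drug=drug).log_ror
    return pd.Series(out)


def generate_geneset_library(
    genes: list[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    planted: dict[str, set[str]] | None = None,
    seed: int = 0,
) -> GeneSetLibrary:
    """Random gene-set library, optionally with planted signal-gene sets.

    Planted sets are guaranteed to contain the specified genes (padded with
    random universe genes up to the drawn size); other sets are uniform draws
    without replacement.
    """
    lo, hi = set_size_range
    if hi > len(genes):
        raise ValueError("set size range exceeds the gene universe")
    if lo < 1 or lo > hi:
        raise ValueError("invalid set size range")
    universe = frozenset(genes)
    planted = planted or {}
    for term, members in planted.items():
        if not set(members) <= universe:
            raise ValueError(f"planted set {term!r} contains genes outside the universe")
    sets: dict[str, frozenset[str]] = {}
    sorted_genes = sorted(genes)
    for si in range(n_sets):
        rng = _rng(seed, _S_SETS, si + 1)
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(sorted_genes, size=size, replace=False)
        sets[f"SET_{si:04d}"] = frozenset(members.tolist())
    for ti, (term, members) in enumerate(sorted(planted.items())):
        rng = _rng(seed, _S_SETS, n_sets + ti + 1)
        size = max(len(members), int(rng.integers(lo, hi + 1)))
        pool = [g for g in sorted_genes if g not in members]
        pad = rng.choice(pool, size=size - len(members), replace=False) if size > len(members) else []
        sets[term] = frozenset(set(members) | set(pad))
    return GeneSetLibrary(sets, universe)


def generate_chem_assets(
    config: SyntheticStudyConfig, true_risk: pd.Series
) -> tuple[list[FingerprintSet], pd.DataFrame]:
    """Cluster-structured fingerprints and a risk-correlated Kd matrix.

    Fingerprints: drugs are assigned round-robin to ``n_fp_clusters``
    prototypes per channel; each bit then flips with probability
    ``fp_mutation_rate``, so within-cluster Tanimoto similarity exceeds
    between-cluster similarity in expectation.

    Kd matrix: a latent promiscuity score is constructed with an in-sample
    Pearson correlation of exactly ``promiscuity_risk_r`` with the risk
    truth; the fraction of the kinase panel bound below 500 nM tracks that
    latent score, with bound kinases drawn log-uniform in (1, 500] nM and
    unbound ones in (1000, 100000] nM.
    """
    drugs = list(true_risk.index)
    n = len(drugs)
    rng = _rng(config.seed, _S_CHEM, 0)
    lengths = {
        "ecfp4": config.fingerprint_length,
        "ecfp2": config.fingerprint_length,
        "daylight": config.fingerprint_length,
        "maccs": 166,
    }
    prototypes = {
        c: rng.random((config.n_fp_clusters, lengths[c])) < 0.3 for c in CHANNELS
    }
    fingerprints = []
    for di, drug in enumerate(drugs):
        d_rng = _rng(config.seed, _S_CHEM, di + 1)
        cluster = di % config.n_fp_clusters
        channels = {}
        for c in CHANNELS:
            bits = prototypes[c][cluster].copy()
            flips = d_rng.random(lengths[c]) < config.fp_mutation_rate
            channels[c] = np.logical_xor(bits, flips)
        fingerprints.append(FingerprintSet(drug, channels))

    # latent promiscuity with exact in-sample correlation to risk
    r_target = config.promiscuity_risk_r
    y = true_risk.to_numpy(dtype=float)
    z = (y - y.mean()) / y.std()
    noise_rng = _rng(config.seed, _S_CHEM, n + 1)
    e = noise_rng.normal(size=n)
    e = e - e.mean() - z * (e @ z) / (z @ z) * 1.0  # center and orthogonalise
    e = e / e.std() if e.std() > 0 else e
    latent = r_target * z + np.sqrt(max(0.0, 1.0 - r_target**2)) * e
    frac = np.clip(0.5 + 0.15 * latent, 0.02, 0.98)

    kinases = [f"K{i:03d}" for i in range(config.n_kinases)]
    kd = np.empty((n, config.n_kinases))
    for di in range(n):
        d_rng = _rng(config.seed, _S_CHEM, n + 2 + di)
        n_bound = int(round(frac[di] * config.n_kinases))
        bound = d_rng.choice(config.n_kinases, size=n_bound, replace=False)
        vals = np.exp(d_rng.uniform(np.log(1000.0), np.log(100_000.0), config.n_kinases))
        vals[bound] = np.exp(d_rng.uniform(np.log(1.0), np.log(500.0), n_bound))
        kd[di] = vals
    return fingerprints, pd.DataFrame(kd, index=drugs, columns=kinases)


def generate_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate every input the pipeline consumes, sharing one drug/gene index."""
    study = generate_expression_study(config)
    true_rors = pd.Series(np.exp(study.true_risk.to_numpy()), index=study.true_risk.index)
    report_table = generate_faers_counts(true_rors, config)
    fingerprints, kd = generate_chem_assets(config, study.true_risk)
    return SyntheticStudy(
        config=config,
        expression=study.expression,
        true_risk=study.true_risk,
        signal_genes=study.signal_genes,
        true_betas=study.true_betas,
        report_table=report_table,
        true_rors=true_rors,
        fingerprints=fingerprints,
        kd_matrix=kd,
    )


def study_regression_dataset(study: SyntheticStudy) -> RegressionDataset:
    """Median drug profiles joined with the risk truth as a regression dataset."""
    tables = list(study.expression.values())
    drugs = study.true_risk.index
    X = pd.DataFrame(
        {d: median_profile(tables, d).median_log_fc for d in drugs}
    ).T
    return RegressionDataset(X, study.true_risk.loc[X.index])
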