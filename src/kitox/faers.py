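"""Clinical risk scoring from spontaneous adverse-event report tables.

Disproportionality analysis for one drug against a comparator class: the
reporting odds ratio (ROR) compares the odds of a target adverse-event group
versus all other events for the drug of interest against the same odds over
all other drugs in the table. The comparator population is whatever the table
contains, so table scope defines the reference class (e.g. "all other kinase
inhibitors").

The risk score handed to downstream regression is the natural-log ROR by
default: it is symmetric around zero and is the scale on which the standard
error is defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AdverseEventReportTable",
    "EventGroupDefinition",
    "EventContingency",
    "RiskScore",
    "ZeroCellError",
    "build_contingency",
    "compute_ror",
    "rank_risk",
    "compare_rankings",
    "classify_phenotypic_assay",
    "normalize_risk",
]


class ZeroCellError(ValueError):
    """A contingency cell is zero and no continuity correction was requested."""


@dataclass(frozen=True)
class AdverseEventReportTable:
    """Long-format report counts: one row per (drug, event term) pair.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``drug``, ``event_term``, ``count`` with non-negative integer
        counts and unique (drug, event_term) pairs.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = {"drug", "event_term", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"report table missing columns: {sorted(missing)}")
        if (df["count"] < 0).any():
            raise ValueError("report counts must be non-negative")
        if df.duplicated(subset=["drug", "event_term"]).any():
            raise ValueError("(drug, event_term) pairs must be unique")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.records["drug"].unique())

    def subset(self, drugs: list[str]) -> "AdverseEventReportTable":
        """Restrict the table (hence the comparator class) to ``drugs``."""
        sub = self.records[self.records["drug"].isin(drugs)].reset_index(drop=True)
        return AdverseEventReportTable(sub)


@dataclass(frozen=True)
class EventGroupDefinition:
    """A flat adverse-event grouping: included terms minus excluded terms.

    Mirrors how heart-failure/cardiomyopathy events are grouped from a
    terminology hierarchy while arrhythmogenic terms are excluded, without
    requiring an ontology engine. Exclusions are applied before inclusion
    counting.
    """

    name: str
    included: frozenset[str]
    excluded: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "included", frozenset(self.included))
        object.__setattr__(self, "excluded", frozenset(self.excluded))
        if self.included & self.excluded:
            raise ValueError(
                f"group '{self.name}': included and excluded terms overlap: "
                f"{sorted(self.included & self.excluded)}"
            )
        if not self.included:
            raise ValueError(f"group '{self.name}' has no included terms")

    @property
    def effective_terms(self) -> frozenset[str]:
        return self.included - self.excluded


@dataclass(frozen=True)
class EventContingency:
    """The four report frequencies behind one drug's risk score.

    f_dt: drug of interest, target-event group
    f_dn: drug of interest, any other event
    f_nt: all other drugs, target-event group
    f_nn: all other drugs, any other event
    """

    f_dt: int
    f_dn: int
    f_nt: int
    f_nn: int

    def __post_init__(self) -> None:
        for name in ("f_dt", "f_dn", "f_nt", "f_nn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_correction(self, add: float = 0.5) -> tuple[float, float, float, float]:
        return (self.f_dt + add, self.f_dn + add, self.f_nt + add, self.f_nn + add)


@dataclass(frozen=True)
class RiskScore:
    drug: str
    ror: float
    log_ror: float
    se_log_ror: float
    ci_low: float
    ci_high: float
    risk_score: float


def build_contingency(
    table: AdverseEventReportTable, drug: str, group: EventGroupDefinition
) -> EventContingency:
    """Tally the 2x2 contingency of ``drug`` x ``group`` over the table.

    The target cell sums counts of the group's included-minus-excluded terms
    for the drug; everything else the drug reported goes to f_dn. The other
    two cells tally the same split over all other drugs in the table.
    """
    df = table.records
    if drug not in set(df["drug"]):
        raise KeyError(f"drug {drug!r} not present in report table")
    terms = group.effective_terms
    if not terms:
        raise ValueError(f"group '{group.name}' is empty after exclusions")

    is_drug = df["drug"] == drug
    is_target = df["event_term"].isin(terms)
    f_dt = int(df.loc[is_drug & is_target, "count"].sum())
    f_dn = int(df.loc[is_drug & ~is_target, "count"].sum())
    f_nt = int(df.loc[~is_drug & is_target, "count"].sum())
    f_nn = int(df.loc[~is_drug & ~is_target, "count"].sum())
    return EventContingency(f_dt, f_dn, f_nt, f_nn)


def compute_ror(
    ct: EventContingency,
    z: float = 1.96,
    drug: str = "",
    zero_correction: bool = False,
    raw_ror_score: bool = False,
) -> RiskScore:
    """Reporting odds ratio with delta-method CI on the log scale.

    ROR = (f_dt/f_dn) / (f_nt/f_nn);
    SE(log ROR) = sqrt(1/f_dt + 1/f_dn + 1/f_nt + 1/f_nn);
    CI = exp(log ROR +/- z * SE).

    Zero cells raise :class:`ZeroCellError` naming the cell unless
    ``zero_correction`` enables the Haldane-Anscombe +0.5 adjustment.
    The ``risk_score`` field is the natural-log ROR unless ``raw_ror_score``.
    """
    cells = {"f_dt": ct.f_dt, "f_dn": ct.f_dn, "f_nt": ct.f_nt, "f_nn": ct.f_nn}
    zeros = [name for name, v in cells.items() if v == 0]
    if zeros and not zero_correction:
        raise ZeroCellError(
            f"zero count in cell(s) {zeros}; enable zero_correction for a "
            "Haldane-Anscombe +0.5 adjustment"
        )
    a, b, c, d = ct.with_correction(0.5) if zeros else (
        float(ct.f_dt), float(ct.f_dn), float(ct.f_nt), float(ct.f_nn)
    )
    ror = (a / b) / (c / d)
    log_ror = float(np.log(ror))
    se = float(np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d))
    ci_low = float(np.exp(log_ror - z * se))
    ci_high = float(np.exp(log_ror + z * se))
    score = float(ror) if raw_ror_score else log_ror
    return RiskScore(drug, float(ror), log_ror, se, ci_low, ci_high, score)


def score_table(
    table: AdverseEventReportTable,
    group: EventGroupDefinition,
    z: float = 1.96,
    zero_correction: bool = False,
    raw_ror_score: bool = False,
) -> list[RiskScore]:
    """Score every drug in the table against all other drugs in it."""
    return [
        compute_ror(
            build_contingency(table, d, group),
            z=z,
            drug=d,
            zero_correction=zero_correction,
            raw_ror_score=raw_ror_score,
        )
        for d in table.drugs
    ]


def rank_risk(scores: list[RiskScore]) -> list[str]:
    """Drugs ordered by descending risk score; ties broken by drug id."""
    if not scores:
        raise ValueError("rank_risk requires at least one score")
    return [s.drug for s in sorted(scores, key=lambda s: (-s.risk_score, s.drug))]


def compare_rankings(a: list[str], b: list[str]) -> float:
    """Spearman rank correlation between two orderings of the same drug set."""
    if set(a) != set(b) or len(a) != len(b):
        raise ValueError("rankings must cover the same drug set")
    pos_b = {d: i for i, d in enumerate(b)}
    rho, _ = stats.spearmanr(np.arange(len(a)), [pos_b[d] for d in a])
    return float(rho)


def classify_phenotypic_assay(
    readouts: dict[str, float],
    risk_ranking: list[str] | None = None,
    threshold: float = 0.20,
) -> tuple[dict[str, bool], float | None]:
    """Binary toxicity calls from phenotypic readouts, plus rank concordance.

    A drug is flagged when its fractional change at the clinical concentration
    exceeds the threshold in magnitude -- strictly ("more than a 20% change"),
    so a change of exactly 0.20 is not flagged. Concordance with a risk
    ranking is the rank-biserial association between flags and risk ranks
    (positive when flagged drugs sit at the high-risk end).
    """
    for d, v in readouts.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite readout for drug {d!r}")
    flags = {d: abs(v) > threshold for d, v in readouts.items()}
    if risk_ranking is None:
        return flags, None
    if set(risk_ranking) != set(readouts):
        raise ValueError("risk ranking must cover the readout drugs")
    n = len(risk_ranking)
    # rank 1 = highest risk; rank-biserial r = 2*(mean rank of unflagged - flagged)/n
    rank = {d: i + 1 for i, d in enumerate(risk_ranking)}
    flagged = [rank[d] for d in readouts if flags[d]]
    unflagged = [rank[d] for d in readouts if not flags[d]]
    if not flagged or not unflagged:
        warnings.warn("all drugs share one flag; concordance undefined")
        return flags, float("nan")
    r_rb = 2.0 * (float(np.mean(unflagged)) - float(np.mean(flagged))) / n
    return flags, r_rb


def normalize_risk(scores: dict[str, float]) -> dict[str, float]:
    """Shift risk scores so the minimum is exactly zero (order-preserving)."""
    if not scores:
        raise ValueError("normalize_risk requires at least one score")
    m = min(scores.values())
    return {d: v - m for d, v in scores.items()}
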