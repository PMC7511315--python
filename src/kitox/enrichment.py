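"""Fisher exact gene-set enrichment and enrichment-risk correlation.

One-tailed (upper / over-representation) Fisher exact tests of per-drug
top-gene lists against a gene-set library, followed by a per-term Pearson
correlation of enrichment strength (-log10 p by default) with the per-drug
clinical risk scores. Terms are retained when at least one drug is enriched
below the p filter and the correlation magnitude clears the r filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetLibrary",
    "EnrichmentResult",
    "TermRiskCorrelation",
    "fisher_enrichment",
    "enrichment_table",
    "correlate_terms_with_risk",
]


@dataclass(frozen=True)
class GeneSetLibrary:
    """Term -> gene-set mapping over a fixed gene universe.

    Sets are intersected with the universe on construction (with a warning
    when genes are dropped), so every stored set is a subset of the universe.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("gene universe is empty")
        trimmed = {}
        dropped = 0
        for term, genes in self.sets.items():
            inside = frozenset(genes) & self.universe
            dropped += len(genes) - len(inside)
            trimmed[term] = inside
        if dropped:
            warnings.warn(f"dropped {dropped} gene-set members outside the universe")
        object.__setattr__(self, "sets", trimmed)
        object.__setattr__(self, "universe", frozenset(self.universe))

    def without_terms(self, blocklist: set[str]) -> "GeneSetLibrary":
        """Drop terms by name (e.g. a user-supplied disease blocklist)."""
        kept = {t: g for t, g in self.sets.items() if t not in blocklist}
        return GeneSetLibrary(kept, self.universe)


@dataclass(frozen=True)
class EnrichmentResult:
    drug: str
    term: str
    overlap: int
    query_size: int
    set_size: int
    universe_size: int
    p: float


@dataclass(frozen=True)
class TermRiskCorrelation:
    term: str
    r: float
    statistic: str  # which per-drug enrichment statistic was correlated
    min_p: float  # minimum enrichment p across drugs
    passes_filters: bool


def _hypergeom_upper_tail(overlap: int, universe: int, set_size: int, query: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, query)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, query))


def fisher_enrichment(
    query: frozenset[str] | set[str],
    library: GeneSetLibrary,
    drug: str = "",
) -> list[EnrichmentResult]:
    """Upper-tail Fisher exact enrichment of a query set against every term.

    p is the probability of observing an overlap at least as large as the
    one seen, under hypergeometric sampling of the query from the universe.
    Query genes outside the universe are trimmed with a warning.
    """
    q = frozenset(query)
    outside = q - library.universe
    if outside:
        warnings.warn(f"trimmed {len(outside)} query genes outside the universe")
        q &= library.universe
    N = len(library.universe)
    results = []
    for term, genes in library.sets.items():
        overlap = len(q & genes)
        p = _hypergeom_upper_tail(overlap, N, len(genes), len(q))
        results.append(EnrichmentResult(drug, term, overlap, len(q), len(genes), N, p))
    return results


def enrichment_table(
    queries: dict[str, frozenset[str] | set[str]], library: GeneSetLibrary
) -> pd.DataFrame:
    """Drug x term matrix of enrichment p-values (long-to-wide convenience)."""
    rows = []
    for drug, query in queries.items():
        for r in fisher_enrichment(query, library, drug=drug):
            rows.append((r.drug, r.term, r.p))
    long = pd.DataFrame(rows, columns=["drug", "term", "p"])
    return long.pivot(index="drug", columns="term", values="p")


def correlate_terms_with_risk(
    per_drug_p: pd.DataFrame,
    risks: pd.Series,
    p_filter: float = 0.05,
    r_filter: float = 0.25,
    statistic: str = "neg_log10_p",
    method: str = "pearson",
) -> list[TermRiskCorrelation]:
    """Correlate per-term enrichment strength with risk scores across drugs.

    ``per_drug_p`` is the drug x term matrix of enrichment p-values. The
    default statistic is -log10(p), so strong enrichment maps to large
    positive values; ``statistic="raw_p"`` correlates the p-values directly.
    A term is flagged as passing when its minimum enrichment p across drugs
    is below ``p_filter`` and |r| exceeds ``r_filter``. Terms with a constant
    statistic across drugs have undefined correlation and are skipped with a
    warning.
    """
    drugs = per_drug_p.index.intersection(risks.index)
    if len(drugs) < 3:
        raise ValueError("need at least three drugs with both enrichment and risk")
    pmat = per_drug_p.loc[drugs]
    y = risks.loc[drugs].to_numpy(dtype=float)
    if statistic == "neg_log10_p":
        xmat = -np.log10(np.clip(pmat.to_numpy(dtype=float), 1e-300, 1.0))
    elif statistic == "raw_p":
        xmat = pmat.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown enrichment statistic {statistic!r}")

    out: list[TermRiskCorrelation] = []
    for j, term in enumerate(pmat.columns):
        x = xmat[:, j]
        if np.ptp(x) == 0.0:
            warnings.warn(f"term {term!r} has constant enrichment across drugs; skipped")
            continue
        if method == "pearson":
            r = float(stats.pearsonr(x, y)[0])
        elif method == "spearman":
            r = float(stats.spearmanr(x, y)[0])
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        min_p = float(pmat[term].min())
        out.append(
            TermRiskCorrelation(
                term=str(term),
                r=r,
                statistic=statistic,
                min_p=min_p,
                passes_filters=bool(min_p < p_filter and abs(r) > r_filter),
            )
        )
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (emitted for transparency only)."""
    return stats.false_discovery_control(np.asarray(p, dtype=float), method="bh")
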