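"""Aggregation and similarity structure of drug perturbation profiles.

Per-cell-line differential-expression tables (log fold-change + p-value per
gene per drug, as produced by a count-based DGE fit) are collapsed to one
profile per drug by taking the per-gene median across the available cell
lines. Ranked top-N gene lists, Jaccard overlap matrices, PCA of absolute
fold-change profiles, and tissue-similarity rankings are computed from these
profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "FoldChangeTable",
    "DrugProfile",
    "RankedGeneList",
    "median_profile",
    "rank_genes",
    "jaccard",
    "jaccard_matrix",
    "pca_profiles",
    "tissue_similarity",
]


@dataclass(frozen=True)
class FoldChangeTable:
    """One cell line's gene x drug log fold-changes with matching p-values."""

    cell_line: str
    log_fc: pd.DataFrame  # genes x drugs
    p_value: pd.DataFrame  # genes x drugs, aligned

    def __post_init__(self) -> None:
        if not self.log_fc.index.equals(self.p_value.index) or not self.log_fc.columns.equals(
            self.p_value.columns
        ):
            raise ValueError("log_fc and p_value tables must share gene/drug indexes")
        if self.log_fc.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        pv = self.p_value.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(pv) < 0 or np.nanmax(pv) > 1:
                raise ValueError("p-values must lie in [0, 1]")
        fc = self.log_fc.to_numpy(dtype=float)
        if np.isinf(fc).any():
            raise ValueError("log fold-changes must be finite")


@dataclass(frozen=True)
class DrugProfile:
    drug: str
    median_log_fc: pd.Series  # indexed by gene
    p_value: pd.Series  # representative (median) p per gene

    @property
    def genes(self) -> pd.Index:
        return self.median_log_fc.index


@dataclass(frozen=True)
class RankedGeneList:
    drug: str
    genes: tuple[str, ...]
    criterion: str  # "p_value" | "abs_fold_change"
    n: int

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def median_profile(
    tables: list[FoldChangeTable], drug: str, p_combine: str = "median"
) -> DrugProfile:
    """Per-gene median log fold-change for one drug across cell lines.

    A gene missing (NaN) in some cell line is summarised over the lines where
    it was measured. The representative p-value is the median across lines by
    default; ``p_combine="fisher"`` combines them with Fisher's method
    instead.
    """
    have = [t for t in tables if drug in t.log_fc.columns]
    if not have:
        raise KeyError(f"drug {drug!r} absent from every fold-change table")
    fc = pd.concat([t.log_fc[drug].rename(t.cell_line) for t in have], axis=1)
    pv = pd.concat([t.p_value[drug].rename(t.cell_line) for t in have], axis=1)
    med_fc = fc.median(axis=1, skipna=True)
    if p_combine == "median":
        rep_p = pv.median(axis=1, skipna=True)
    elif p_combine == "fisher":
        from scipy import stats

        def _fisher(row: pd.Series) -> float:
            vals = row.dropna().to_numpy()
            if vals.size == 0:
                return float("nan")
            return float(stats.combine_pvalues(np.clip(vals, 1e-300, 1.0))[1])

        rep_p = pv.apply(_fisher, axis=1)
    else:
        raise ValueError(f"unknown p_combine rule {p_combine!r}")
    return DrugProfile(drug, med_fc, rep_p)


def rank_genes(profile: DrugProfile, n: int, criterion: str = "p_value") -> RankedGeneList:
    """Top-n genes by ascending p or descending |median FC|.

    Ties break by larger |FC|, then lexicographic gene id, so output is
    deterministic and prefix-stable (a larger n extends, never reorders).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    genes = profile.genes
    abs_fc = profile.median_log_fc.abs()
    if criterion == "p_value":
        order = sorted(genes, key=lambda g: (profile.p_value[g], -abs_fc[g], g))
    elif criterion == "abs_fold_change":
        order = sorted(genes, key=lambda g: (-abs_fc[g], g))
    else:
        raise ValueError(f"unknown ranking criterion {criterion!r}")
    if n > len(genes):
        warnings.warn(
            f"requested top {n} of {len(genes)} genes; returning the full list"
        )
        n = len(genes)
    return RankedGeneList(profile.drug, tuple(order[:n]), criterion, n)


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """|A intersect B| / |A union B|."""
    if not a or not b:
        raise ValueError("Jaccard index of an empty gene set is undefined")
    return len(set(a) & set(b)) / len(set(a) | set(b))


def jaccard_matrix(lists: list[RankedGeneList]) -> pd.DataFrame:
    """Symmetric drug x drug matrix of Jaccard indices of top-gene sets."""
    if len(lists) < 2:
        raise ValueError("need at least two ranked lists")
    sets = {rl.drug: rl.as_set() for rl in lists}
    drugs = [rl.drug for rl in lists]
    m = pd.DataFrame(np.eye(len(drugs)), index=drugs, columns=drugs)
    for i, di in enumerate(drugs):
        for dj in drugs[i + 1 :]:
            v = jaccard(sets[di], sets[dj])
            m.loc[di, dj] = v
            m.loc[dj, di] = v
    return m


def pca_profiles(
    profiles: list[DrugProfile], k: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the drugs x genes matrix of absolute median fold-changes.

    The matrix is column-centered but not variance-scaled, preserving effect
    magnitudes. Returns per-drug coordinates on the first k components and
    the explained-variance fractions (non-increasing).
    """
    if len(profiles) < 2:
        raise ValueError("PCA needs at least two drug profiles")
    X = pd.DataFrame(
        {p.drug: p.median_log_fc.abs() for p in profiles}
    ).T  # drugs x genes
    if k > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError(f"k={k} too large for a {X.shape} profile matrix")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X.to_numpy())
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=X.index, columns=cols), pca.explained_variance_ratio_


def tissue_similarity(
    query_top_genes: frozenset[str] | set[str],
    tissue_samples: dict[str, list[frozenset[str] | set[str]]],
) -> tuple[pd.DataFrame, list[str]]:
    """Rank tissues by median Jaccard similarity of top-gene sets.

    ``tissue_samples`` maps tissue name -> per-sample top-gene sets (the
    binary top-500-gene membership encoding: Jaccard of indicator vectors
    equals Jaccard of the sets). Returns the long table of per-sample
    similarities and the tissues ordered by descending median similarity
    (ties broken by tissue name).
    """
    if not query_top_genes:
        raise ValueError("query gene set is empty")
    if not tissue_samples:
        raise ValueError("no tissue groups supplied")
    rows = []
    for tissue, samples in tissue_samples.items():
        if not samples:
            raise ValueError(f"tissue {tissue!r} has no samples")
        for i, s in enumerate(samples):
            rows.append((tissue, i, jaccard(query_top_genes, s)))
    table = pd.DataFrame(rows, columns=["tissue", "sample", "jaccard"])
    med = table.groupby("tissue")["jaccard"].median()
    ranking = sorted(med.index, key=lambda t: (-med[t], t))
    return table, ranking
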