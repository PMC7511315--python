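"""Chemical structure and kinase-binding-profile risk structuring.

Pairwise chemical similarity between inhibitors is a weighted average of
Tanimoto coefficients over four fingerprint channels (circular radius-2 and
radius-1, path-based, and structural-key), weighted 30/30/30/10 by default.
A structure-activity-similarity (SAS) map pairs that similarity with the
difference in cardiotoxicity scores (DCS) and labels each pair's quadrant;
highly similar pairs with a large risk difference are activity cliffs.
Kinase-binding breadth is summarised by a selectivity score (fraction of
assayed kinases bound below a Kd threshold), and its correlation with risk
quantifies the promiscuity-toxicity relationship.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CHANNELS",
    "FingerprintSet",
    "WeightedTcConfig",
    "SASMap",
    "KdProfile",
    "tanimoto",
    "weighted_tanimoto",
    "build_sas_map",
    "selectivity_score",
    "kd_transform",
    "cluster_by_chemical_similarity",
    "linkage_to_newick",
    "promiscuity_risk_correlation",
    "fingerprint_adapter",
]

#: The four fingerprint channels, in weight order.
CHANNELS = ("ecfp4", "ecfp2", "daylight", "maccs")


@dataclass(frozen=True)
class FingerprintSet:
    """One molecule's four named binary fingerprints."""

    molecule: str
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown fingerprint channels: {sorted(unknown)}")
        fixed = {}
        for name, bits in self.channels.items():
            arr = np.asarray(bits, dtype=bool)
            if arr.size == 0:
                raise ValueError(f"channel {name!r} is empty")
            fixed[name] = arr
        object.__setattr__(self, "channels", fixed)


@dataclass(frozen=True)
class WeightedTcConfig:
    """Per-channel weights; non-negative and summing to one."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.weights) != set(CHANNELS):
            raise ValueError(f"weights must cover exactly the channels {CHANNELS}")
        vals = np.array([self.weights[c] for c in CHANNELS], dtype=float)
        if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    @classmethod
    def default(cls) -> "WeightedTcConfig":
        return cls({"ecfp4": 0.3, "ecfp2": 0.3, "daylight": 0.3, "maccs": 0.1})


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| for equal-length bit-vectors; 0 if both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"bit-vector lengths differ: {a.size} vs {b.size}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        warnings.warn("Tanimoto of two all-zero vectors; defined as 0")
        return 0.0
    return int(np.logical_and(a, b).sum()) / union


def weighted_tanimoto(
    fps_a: FingerprintSet, fps_b: FingerprintSet, config: WeightedTcConfig | None = None
) -> float:
    """Convex combination of per-channel Tanimoto coefficients."""
    config = config or WeightedTcConfig.default()
    missing = [c for c in CHANNELS if c not in fps_a.channels or c not in fps_b.channels]
    if missing:
        raise KeyError(f"fingerprint channel(s) missing: {missing}")
    return sum(
        config.weights[c] * tanimoto(fps_a.channels[c], fps_b.channels[c])
        for c in CHANNELS
    )


@dataclass(frozen=True)
class SASMap:
    """All pairwise (similarity, risk-difference) records with quadrant labels."""

    pairs: pd.DataFrame  # mol_i, mol_j, tc, dcs, quadrant
    sim_threshold: float
    dcs_threshold: float


_QUADRANTS = {
    (False, True): "upper_left",
    (False, False): "lower_left",
    (True, False): "smooth_sar",
    (True, True): "activity_cliff",
}


def build_sas_map(
    molecules: list[FingerprintSet],
    risks: dict[str, float],
    sim_rule="percentile_90",
    dcs_rule="half_max",
    config: WeightedTcConfig | None = None,
) -> SASMap:
    """Score all unordered pairs and label SAS quadrants.

    The similarity threshold is the 90th percentile of the pairwise weighted
    Tc distribution (``sim_rule="percentile_90"``, the top-10% rule) or a
    fixed value; the risk-difference threshold is half the maximum DCS
    (``dcs_rule="half_max"``) or a fixed value. A pair strictly above both
    thresholds is an activity cliff; exactly-at-threshold pairs fall on the
    low side.
    """
    if len(molecules) < 2:
        raise ValueError("need at least two molecules")
    missing = [m.molecule for m in molecules if m.molecule not in risks]
    if missing:
        raise KeyError(f"risk scores missing for: {missing}")
    rows = []
    for a, b in combinations(sorted(molecules, key=lambda m: m.molecule), 2):
        tc = weighted_tanimoto(a, b, config)
        dcs = abs(risks[a.molecule] - risks[b.molecule])
        rows.append((a.molecule, b.molecule, tc, dcs))
    df = pd.DataFrame(rows, columns=["mol_i", "mol_j", "tc", "dcs"])

    if sim_rule == "percentile_90":
        t_sim = float(np.percentile(df["tc"], 90))
    else:
        t_sim = float(sim_rule)
    if dcs_rule == "half_max":
        t_dcs = float(df["dcs"].max()) / 2.0
        if t_dcs == 0.0:
            warnings.warn("constant risks: DCS threshold 0; all pairs in lower half")
    else:
        t_dcs = float(dcs_rule)

    df["quadrant"] = [
        _QUADRANTS[(tc > t_sim, dcs > t_dcs)] for tc, dcs in zip(df["tc"], df["dcs"])
    ]
    return SASMap(df, t_sim, t_dcs)


@dataclass(frozen=True)
class KdProfile:
    """One molecule's kinase dissociation constants in nM (NaN = not assayed)."""

    molecule: str
    kd: pd.Series

    def __post_init__(self) -> None:
        vals = self.kd.to_numpy(dtype=float)
        if (vals[~np.isnan(vals)] <= 0).any():
            raise ValueError("Kd values must be positive where present")


def selectivity_score(profile: KdProfile, kd_threshold: float = 500.0) -> tuple[float, int]:
    """Fraction of assayed kinases bound at or below ``kd_threshold`` nM.

    A score near 1 marks a promiscuous inhibitor, near 0 a selective one.
    Returns (score, raw bound-target count); unassayed kinases are excluded
    from both numerator and denominator.
    """
    vals = profile.kd.dropna()
    if vals.empty:
        raise ValueError(f"no assayed kinases for {profile.molecule!r}")
    bound = int((vals <= kd_threshold).sum())
    return bound / len(vals), bound


def kd_transform(kd: float) -> float:
    """-log10(Kd / 1e5) for Kd in nM; the divisor keeps nM-scale values non-negative."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    return float(-np.log10(kd / 100_000.0))


def cluster_by_chemical_similarity(tc_matrix: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Average-linkage agglomerative clustering on distance 1 - Tc.

    Returns the deterministic leaf order and the scipy linkage matrix.
    """
    m = tc_matrix.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("Tc matrix must be square and symmetric")
    # lexicographic input order makes scipy's tie-breaking deterministic
    ids = sorted(tc_matrix.index)
    dist = 1.0 - tc_matrix.loc[ids, ids].to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(Z)
    return [ids[i] for i in leaves], Z


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy merge tree as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return render(tree, tree.dist) + ";"


def promiscuity_risk_correlation(
    selectivity: dict[str, float], risks: dict[str, float]
) -> tuple[float, float]:
    """Pearson correlation (and two-sided p) of binding promiscuity with risk."""
    common = sorted(set(selectivity) & set(risks))
    if len(common) < 3:
        raise ValueError("need at least three molecules with both scores")
    x = np.array([selectivity[m] for m in common])
    y = np.array([risks[m] for m in common])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fingerprint_adapter(smiles: dict[str, str]) -> tuple[list[FingerprintSet], dict[str, str]]:
    """Fingerprint SMILES strings into the four channels via a chemistry toolkit.

    Channels: circular radius-2 (2048 bits), circular radius-1 (2048 bits),
    path-based hashed (2048 bits), and 166-key structural. Returns the
    fingerprint sets plus a per-molecule error map for unparseable inputs.
    This is the only operation that requires ``rdkit``.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.*")
    morgan2 = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    morgan1 = rdFingerprintGenerator.GetMorganGenerator(radius=1, fpSize=2048)
    rdkgen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)
    out: list[FingerprintSet] = []
    errors: dict[str, str] = {}
    for mol_id, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            errors[mol_id] = f"unparseable SMILES: {smi!r}"
            continue
        out.append(
            FingerprintSet(
                mol_id,
                {
                    "ecfp4": np.array(morgan2.GetFingerprint(mol), dtype=bool),
                    "ecfp2": np.array(morgan1.GetFingerprint(mol), dtype=bool),
                    "daylight": np.array(rdkgen.GetFingerprint(mol), dtype=bool),
                    "maccs": np.array(MACCSkeys.GenMACCSKeys(mol), dtype=bool),
                },
            )
        )
    return out, errors
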