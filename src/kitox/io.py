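"""Readers and writers for the pipeline's plain-text interchange formats.

TSV for report tables, fold-change/p-value matrices, risk scores, Kd
matrices and pair tables; GMT for gene-set libraries; YAML/JSON for event
groups; a simple ``id TAB channel TAB hex-bitstring`` format for
fingerprints; JSON for signature models. Floats are written with 12
significant digits so identical runs produce byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chem import CHANNELS, FingerprintSet, KdProfile
from .enrichment import GeneSetLibrary
from .expression import FoldChangeTable
from .faers import AdverseEventReportTable, EventGroupDefinition, RiskScore

FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------- report tables

def read_report_table(path: str | Path) -> AdverseEventReportTable:
    df = pd.read_csv(path, sep="\t", dtype={"drug": str, "event_term": str})
    return AdverseEventReportTable(df)


def write_report_table(table: AdverseEventReportTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_event_group(path: str | Path) -> EventGroupDefinition:
    """Event group as YAML/JSON: keys ``name``, ``included``, ``excluded``."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return EventGroupDefinition(
        d["name"], frozenset(d["included"]), frozenset(d.get("excluded", []))
    )


def write_risk_scores(scores: list[RiskScore], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (s.drug, s.ror, s.log_ror, s.se_log_ror, s.ci_low, s.ci_high, s.risk_score)
            for s in scores
        ],
        columns=["drug", "ror", "log_ror", "se", "ci_low", "ci_high", "risk_score"],
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_risk_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="drug")


# ------------------------------------------------------------ expression tables

def read_fold_change_table(
    path: str | Path, cell_line: str | None = None
) -> FoldChangeTable:
    """Long-format TSV with columns gene, drug, logFC, pvalue."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "drug": str})
    fc = df.pivot(index="gene", columns="drug", values="logFC")
    pv = df.pivot(index="gene", columns="drug", values="pvalue")
    return FoldChangeTable(cell_line or Path(path).stem, fc, pv)


def write_fold_change_table(table: FoldChangeTable, path: str | Path) -> None:
    long = (
        table.log_fc.stack()
        .rename("logFC")
        .to_frame()
        .join(table.p_value.stack().rename("pvalue"))
        .reset_index()
    )
    long.columns = ["gene", "drug", "logFC", "pvalue"]
    long.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ----------------------------------------------------------------------- GMT

def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetLibrary:
    """Standard GMT: term TAB description TAB gene TAB gene ...

    If no universe is supplied, the union of all set members is used.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetLibrary(sets, frozenset(universe))


def write_gmt(library: GeneSetLibrary, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term in sorted(library.sets):
            genes = "\t".join(sorted(library.sets[term]))
            fh.write(f"{term}\t{description}\t{genes}\n")


# --------------------------------------------------------------- fingerprints

def _to_hex(bits: np.ndarray) -> str:
    return np.packbits(bits.astype(np.uint8)).tobytes().hex()


def _from_hex(text: str, n_bits: int) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(text), dtype=np.uint8)
    return np.unpackbits(raw)[:n_bits].astype(bool)


def write_fingerprints(fps: list[FingerprintSet], path: str | Path) -> None:
    """Rows of ``molecule TAB channel TAB n_bits TAB hex-encoded bits``."""
    with open(path, "w") as fh:
        for fp in fps:
            for c in CHANNELS:
                bits = fp.channels[c]
                fh.write(f"{fp.molecule}\t{c}\t{bits.size}\t{_to_hex(bits)}\n")


def read_fingerprints(path: str | Path) -> list[FingerprintSet]:
    by_mol: dict[str, dict[str, np.ndarray]] = {}
    with open(path) as fh:
        for line in fh:
            mol, channel, n_bits, hexed = line.rstrip("\n").split("\t")
            by_mol.setdefault(mol, {})[channel] = _from_hex(hexed, int(n_bits))
    return [FingerprintSet(mol, ch) for mol, ch in by_mol.items()]


def read_smiles(path: str | Path) -> dict[str, str]:
    """One molecule per line: ``id TAB smiles``."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            mol, smi = line.split("\t")
            out[mol] = smi
    return out


# ------------------------------------------------------------------ Kd matrix

def read_kd_matrix(path: str | Path) -> pd.DataFrame:
    """Drug rows x kinase columns, Kd in nM; blank cells mean not assayed."""
    return pd.read_csv(path, sep="\t", index_col=0)


def kd_profiles(matrix: pd.DataFrame) -> list[KdProfile]:
    return [KdProfile(str(d), matrix.loc[d]) for d in matrix.index]
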