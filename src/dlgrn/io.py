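"""Delimited-text I/O for expression matrices, edge tables and gold standards.

All artifacts are plain tab- or comma-separated text (delimiter
auto-detected): matrices are samples x genes with a header row of gene
identifiers and an optional first column of sample identifiers; gold
standards are two-column regulator -> target lists; numeric output is
written with 6 significant digits.
"""
from __future__ import annotations

import logging
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import GoldStandard

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_regulators",
    "read_gold",
    "write_matrix",
    "write_edges",
    "read_edges",
    "align_samples",
]

FLOAT_FORMAT = "%.6g"


def _detect_delimiter(path) -> str:
    first = Path(path).open().readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_matrix(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_delimiter(path)
    header = Path(path).open().readline().rstrip("\n").split(sep)
    names = [h for h in header if h]  # a leading empty cell is the index corner
    dups = {h for h in names if names.count(h) > 1}
    if dups:
        raise ValueError(f"{path}: duplicate identifiers {sorted(dups)}")
    df = pd.read_csv(path, sep=sep)
    # optional sample-ID column: first column non-numeric
    if df.shape[1] and not pd.api.types.is_numeric_dtype(df.iloc[:, 0]):
        df = df.set_index(df.columns[0])
        df.index.name = None
    bad = df.columns[~df.apply(pd.api.types.is_numeric_dtype)]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(
            f"{path}: non-numeric cell at row {row!r}, column {col!r}"
        )
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing/ragged value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate identifiers {dups}")
    return df.astype(float)


def read_expression(path) -> pd.DataFrame:
    """Read a samples x genes expression matrix (needs >= 2 samples)."""
    df = _read_matrix(path)
    if df.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    return df


def read_regulators(path) -> pd.DataFrame:
    """Read a samples x regulators matrix (TF expression or methylation)."""
    return _read_matrix(path)


def align_samples(expr: pd.DataFrame, regs: pd.DataFrame) -> pd.DataFrame:
    """Align the regulator matrix to the expression matrix's sample order.

    Alignment is by sample identifier when both matrices carry them, by row
    count (with a warning) otherwise.
    """
    expr_ids = expr.index.astype(str)
    reg_ids = regs.index.astype(str)
    default_expr = (expr_ids == pd.RangeIndex(len(expr)).astype(str)).all()
    default_regs = (reg_ids == pd.RangeIndex(len(regs)).astype(str)).all()
    if not default_expr and not default_regs:
        missing = set(expr_ids) - set(reg_ids)
        if missing:
            raise ValueError(f"sample-count mismatch: regulators lack samples {sorted(missing)[:5]}")
        return regs.loc[expr_ids]
    if len(expr) != len(regs):
        raise ValueError(
            f"sample-count mismatch: {len(expr)} expression vs {len(regs)} regulator rows"
        )
    logger.warning("no shared sample identifiers; aligning regulators by row order")
    return regs


def read_gold(path) -> GoldStandard:
    """Read a two-column regulator -> target edge list; self-edges dropped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (regulator, target)")
    # tolerate a header row
    if df.iloc[0, 0] in ("regulator", "source", "tf") or df.iloc[0, 1] in ("target", "gene"):
        df = df.iloc[1:]
    pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    self_edges = sum(1 for r, t in pairs if r == t)
    if self_edges:
        logger.warning("dropped %d self-edge record(s) from %s", self_edges, path)
    return GoldStandard(edges={(r, t) for r, t in pairs if r != t})


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a matrix as tab-separated text with 6 significant digits."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_edges(table: pd.DataFrame, path) -> None:
    """Write an edge-score table (regulator, target, cs[, p_value]) sorted by
    cs descending."""
    cols = [c for c in ("regulator", "target", "cs", "p_value") if c in table.columns]
    out = table[cols]
    if "cs" in cols:
        out = out.sort_values(
            ["cs", "regulator", "target"], ascending=[False, True, True], kind="stable"
        )
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_edges(path) -> pd.DataFrame:
    """Read back an edge-score table written by :func:`write_edges`."""
    df = pd.read_csv(path, sep=_detect_delimiter(path))
    required = {"regulator", "target", "cs"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df
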