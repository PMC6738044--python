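"""Delimited-text I/O for peptide matrices, sample tables and reports.

On disk the peptide matrix is wide TSV with peptides as rows (peak lists are
tabulated that way, and peptide count far exceeds sample count); in memory
rows are samples.  All files are UTF-8, tab-separated, ``.`` decimal.
Empty intensity cells mean "not detected" and are stored as 0.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (FEATURE_COLUMNS, FormatError, ParseError, PeptideMatrix,
                    SampleTable, SplitAssignment, ValidationError)

SEP = "\t"


def read_peptide_matrix(path: str | Path, scale: str = "raw") -> PeptideMatrix:
    """Read a wide peptide-list TSV into a validated matrix.

    Expected columns: ``peptide_id  mass_kda  migration_min
    is_internal_standard  <sample_1> ... <sample_n>``.  On the raw and
    normalised scales empty cells mean "not detected" and become 0; on the
    log scale non-detects are stored as ``-inf``.
    """
    df = pd.read_csv(path, sep=SEP, dtype=str, keep_default_na=False)
    if list(df.columns[:4]) != FEATURE_COLUMNS:
        raise FormatError(
            f"{path}: header must start with {FEATURE_COLUMNS}, "
            f"got {list(df.columns[:4])}")
    sample_ids = list(df.columns[4:])
    if not sample_ids:
        raise FormatError(f"{path}: no sample columns")

    features = df[FEATURE_COLUMNS].copy()
    for col in ("mass_kda", "migration_min"):
        features[col] = _numeric(features[col], path, col)
    features["is_internal_standard"] = _boolean(
        features["is_internal_standard"], path)

    empty = "0" if scale != "log" else "-inf"  # empty cell = not detected
    intensity = np.empty((len(sample_ids), len(df)))
    for j, sid in enumerate(sample_ids):
        col = df[sid].str.strip().replace("", empty)
        intensity[j] = _numeric(col, path, sid, index=df["peptide_id"],
                                allow_negative=(scale == "log"))
    return PeptideMatrix(sample_ids=sample_ids, features=features,
                         values=intensity, scale=scale)


def write_peptide_matrix(matrix: PeptideMatrix, path: str | Path) -> None:
    """Write the wide TSV form; full float precision, round-trip exact."""
    meta = matrix.features.copy()
    meta["is_internal_standard"] = meta["is_internal_standard"].astype(bool)
    body = pd.DataFrame(matrix.values.T, columns=matrix.sample_ids)
    pd.concat([meta.reset_index(drop=True), body], axis=1).to_csv(
        path, sep=SEP, index=False)


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a sample-annotation table (TSV or comma CSV by extension)."""
    sep = "," if str(path).endswith(".csv") else SEP
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in ("dre_positive", "fivear_inhibitor"):
        if col in df.columns:
            df[col] = _boolean(df[col].astype(str), path)
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else SEP
    samples.df.to_csv(path, sep=sep, index=False)


def read_split(path: str | Path, seed: int = 0) -> SplitAssignment:
    df = pd.read_csv(path, sep=SEP)
    disc = list(df.loc[df["subset"] == "discovery", "sample_id"])
    val = list(df.loc[df["subset"] == "validation", "sample_id"])
    return SplitAssignment(disc, val, seed=seed)


def write_split(split: SplitAssignment, path: str | Path) -> None:
    df = pd.DataFrame({
        "sample_id": split.discovery_ids + split.validation_ids,
        "subset": (["discovery"] * len(split.discovery_ids)
                   + ["validation"] * len(split.validation_ids)),
    })
    df.to_csv(path, sep=SEP, index=False)


def write_report(tables: dict[str, pd.DataFrame], path: str | Path,
                 summary: str | None = None) -> None:
    """Write each result table as TSV plus an optional human-readable summary.

    Deterministic: identical inputs produce byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(path / f"{name}.tsv", sep=SEP, index=False)
    if summary is not None:
        (path / "summary.txt").write_text(summary, encoding="utf-8")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def _numeric(col: pd.Series, path, name, index=None,
             allow_negative: bool = False) -> np.ndarray:
    vals = pd.to_numeric(col, errors="coerce")
    bad = vals.isna() & (col.astype(str).str.strip() != "")
    if bad.any():
        where = (index[bad].iloc[0] if index is not None
                 else f"row {int(np.flatnonzero(bad)[0]) + 2}")
        raise ParseError(
            f"{path}: non-numeric value {col[bad].iloc[0]!r} in column "
            f"{name!r} at {where}")
    if vals.isna().any():
        raise ParseError(f"{path}: empty value in column {name!r}")
    # numpy's parser is correctly rounded (bit-exact round trips); pandas'
    # fast to_numeric path is only used above to locate malformed cells
    out = col.to_numpy(dtype=object).astype(float)
    if (not allow_negative and name not in ("mass_kda", "migration_min")
            and (out < 0).any()):
        raise ValidationError(f"{path}: negative intensity in column {name!r}")
    return out


_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


def _boolean(col: pd.Series, path) -> np.ndarray:
    low = col.astype(str).str.strip().str.lower()
    bad = ~low.isin(_TRUE | _FALSE)
    if bad.any():
        raise ParseError(
            f"{path}: non-boolean value {col[bad].iloc[0]!r} "
            f"(expected true/false, 1/0, yes/no)")
    return low.isin(_TRUE).to_numpy()
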