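"""Delimited-text readers/writers for concentration, metadata and result tables.

CSV vs TSV is autodetected from the file extension (.tsv/.txt -> tab,
anything else -> comma).  Empty cells (or a configurable sentinel) denote
missing concentrations; numbers are written with 12 significant digits so
round-trips preserve p/q values far below any tolerance used downstream.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ConcentrationMatrix, FormatError, ValidationError

log = logging.getLogger("hypoxmet")

FLOAT_FMT = "%.12g"


def _sep_for(path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","


def _read_header(path: Path, sep: str) -> list:
    with open(path, newline="") as fh:
        row = next(csv.reader(fh, delimiter=sep))
    return row


def read_sample_meta(path) -> pd.DataFrame:
    """Read a sample-metadata table (sample_id, animal_id, group, timepoint, hypoxia_duration)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str, "animal_id": str})
    required = {"sample_id", "animal_id", "group", "timepoint", "hypoxia_duration"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample metadata {path} lacks columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"duplicate sample_id in {path}")
    return df.set_index("sample_id")


def read_analyte_meta(path) -> pd.DataFrame:
    """Read an analyte-annotation table (analyte_id, analyte_class[, display_name])."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if "class" in df.columns and "analyte_class" not in df.columns:
        df = df.rename(columns={"class": "analyte_class"})
    required = {"analyte_id", "analyte_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"analyte metadata {path} lacks columns {sorted(missing)}")
    if df["analyte_id"].duplicated().any():
        raise FormatError(f"duplicate analyte_id in {path}")
    if "display_name" not in df.columns:
        df["display_name"] = df["analyte_id"]
    df["display_name"] = df["display_name"].fillna(df["analyte_id"])
    return df.set_index("analyte_id")


def read_concentration_table(
    path,
    analyte_meta_path,
    sample_meta_path,
    missing_sentinel: str = "",
    long_format: bool = False,
) -> ConcentrationMatrix:
    """Read a wide concentration table plus its metadata into a ConcentrationMatrix.

    The wide layout has sample_id in the first column and one column per
    analyte.  ``long_format=True`` accepts (sample_id, analyte_id, value)
    triples instead, as some LIMS exports produce.
    """
    path = Path(path)
    sep = _sep_for(path)
    na_values = [v for v in {"", missing_sentinel, "NA", "NaN", "nan"} if v is not None]

    if long_format:
        long_df = pd.read_csv(path, sep=sep, na_values=na_values, keep_default_na=False, dtype={"sample_id": str, "analyte_id": str})
        need = {"sample_id", "analyte_id", "value"}
        if not need <= set(long_df.columns):
            raise FormatError(f"long-format table {path} lacks columns {sorted(need - set(long_df.columns))}")
        if long_df.duplicated(["sample_id", "analyte_id"]).any():
            raise FormatError(f"duplicate (sample_id, analyte_id) pairs in {path}")
        values = long_df.pivot(index="sample_id", columns="analyte_id", values="value")
    else:
        header = _read_header(path, sep)
        analyte_cols = header[1:]
        if len(set(analyte_cols)) != len(analyte_cols):
            dupes = sorted({a for a in analyte_cols if analyte_cols.count(a) > 1})
            raise FormatError(f"analyte_id repeated in header of {path}: {dupes}")
        values = pd.read_csv(path, sep=sep, index_col=0, na_values=na_values, keep_default_na=False)
        values.index = values.index.astype(str)
        if values.index.duplicated().any():
            raise FormatError(f"duplicate sample_id in {path}")

    try:
        values = values.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric concentration cell in {path}: {exc}") from None
    if np.nanmin(values.to_numpy(), initial=0.0) < 0:
        raise ValidationError(f"negative concentration in {path}")

    samples = read_sample_meta(sample_meta_path)
    analytes = read_analyte_meta(analyte_meta_path)

    unknown_samples = values.index.difference(samples.index)
    if len(unknown_samples):
        raise KeyError(f"samples without metadata: {list(unknown_samples[:5])}")
    unknown_analytes = values.columns.difference(analytes.index)
    if len(unknown_analytes):
        raise KeyError(f"analytes without metadata: {list(unknown_analytes[:5])}")

    return ConcentrationMatrix(values, samples.loc[values.index], analytes.loc[values.columns])


def write_concentration_matrix(cm: ConcentrationMatrix, table_path, analyte_meta_path=None, sample_meta_path=None) -> None:
    """Write the wide table (empty cell = missing) and, optionally, its metadata tables."""
    sep = _sep_for(table_path)
    cm.values.to_csv(table_path, sep=sep, float_format=FLOAT_FMT, index_label="sample_id", na_rep="")
    if sample_meta_path is not None:
        cm.samples.to_csv(sample_meta_path, sep=_sep_for(sample_meta_path), float_format=FLOAT_FMT, index_label="sample_id")
    if analyte_meta_path is not None:
        cm.analytes.to_csv(analyte_meta_path, sep=_sep_for(analyte_meta_path), index_label="analyte_id")


def write_result_table(results, path) -> None:
    """Write a result table (list of dicts / DataFrame) as delimited text.

    Column order is deterministic: the canonical statistics columns first, then
    any extras in first-seen order.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        results = list(results)
        if not results:
            raise ValidationError("refusing to write an empty result table")
        df = pd.DataFrame(results)
    if df.empty:
        raise ValidationError("refusing to write an empty result table")
    canonical = [c for c in ("feature_id", "statistic", "estimate", "p_value", "q_value", "fold_change") if c in df.columns]
    rest = [c for c in df.columns if c not in canonical]
    df = df[canonical + rest]
    bad = [c for c in ("p_value", "q_value") if c in df.columns and ((df[c].dropna() < 0).any() or (df[c].dropna() > 1).any())]
    if bad:
        raise ValidationError(f"columns outside [0,1]: {bad}")
    df.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FMT, index=False)


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path))
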