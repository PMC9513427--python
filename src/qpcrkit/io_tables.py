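"""Reading, validation and writing of qPCR input/result tables.

All tables are plain :class:`pandas.DataFrame` objects with a fixed internal
schema (long format, one reaction per row for Cq data).  Readers accept a
``column_map`` translating user column names onto the internal schema, so
exports from different qPCR machines can be ingested without renaming files
by hand.

Internal schemas
----------------
Cq table            ``gene, group, bio_rep, tech_rep, cq`` (``cq`` is NaN for
                    wells that did not amplify / were flagged by the machine)
dilution table      ``gene, rel_conc, cq``
concentration table ``sample, conc`` (one row per replicate measurement)
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CQ_COLUMNS = ["gene", "group", "bio_rep", "tech_rep", "cq"]
DILUTION_COLUMNS = ["gene", "rel_conc", "cq"]
CONC_COLUMNS = ["sample", "conc"]

#: Cell values treated as a missing Cq (case-insensitive), on top of empty cells.
MISSING_CQ_TOKENS = {"", "na", "n/a", "nan", "undetermined", "undet."}


class TableSchemaError(ValueError):
    """A required column is missing or a value violates the schema."""


class DuplicateRowError(ValueError):
    """Duplicate (gene, group, bio_rep, tech_rep) combinations after ingestion."""


def _read_any(path, dialect=None, sheet=None) -> pd.DataFrame:
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower().lstrip(".")
        dialect = {"tsv": "tsv", "txt": "tsv", "xlsx": "xlsx", "xls": "xlsx"}.get(suffix, "csv")
    if dialect == "csv":
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect == "tsv":
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "xlsx":
        return pd.read_excel(path, sheet_name=sheet if sheet is not None else 0, dtype=str)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _apply_column_map(df: pd.DataFrame, column_map, required, optional=()) -> pd.DataFrame:
    column_map = dict(column_map or {})
    rename = {}
    for schema_name in list(required) + list(optional):
        user_name = column_map.get(schema_name, schema_name)
        if user_name in df.columns:
            rename[user_name] = schema_name
        elif schema_name in required:
            raise TableSchemaError(
                f"required column {user_name!r} (schema field {schema_name!r}) "
                f"not found; available: {list(df.columns)}"
            )
    return df.rename(columns=rename)


def _parse_cq(value) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    s = str(value).strip()
    if s.lower() in MISSING_CQ_TOKENS:
        return math.nan
    try:
        return float(s)
    except ValueError:
        return math.nan


def read_cq_table(path, column_map=None, dialect=None, sheet=None) -> pd.DataFrame:
    """Read a long-format Cq table (one reaction per row).

    Rows whose Cq cell is empty or a recognized "no amplification" token
    ("NA", "Undetermined", "Undet.", case-insensitive) are retained with
    ``cq = NaN`` so that downstream pairing checks can report them.

    Parameters
    ----------
    column_map : dict, optional
        Maps internal schema names (``gene``, ``group``, ``bio_rep``,
        ``tech_rep``, ``cq``) to the column names used in the file.
    """
    raw = _read_any(path, dialect, sheet)
    df = _apply_column_map(raw, column_map, required=["gene", "group", "bio_rep", "cq"],
                           optional=["tech_rep"])
    if "tech_rep" not in df.columns:
        df["tech_rep"] = 1
    df = df[CQ_COLUMNS].copy()
    df["cq"] = df["cq"].map(_parse_cq)
    return validate_cq_table(df)


def validate_cq_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory Cq table against the internal schema."""
    df = df.copy()
    if "tech_rep" not in df.columns:
        df["tech_rep"] = 1
    missing_cols = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TableSchemaError(f"Cq table missing columns: {missing_cols}")
    df = df[CQ_COLUMNS]
    empty = (df["gene"].astype(str).str.strip() == "") | (df["group"].astype(str).str.strip() == "")
    if empty.any():
        raise TableSchemaError(f"{int(empty.sum())} rows have empty gene or group labels")
    df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
    bad = df["cq"].notna() & ((df["cq"] <= 0) | ~np.isfinite(df["cq"]))
    if bad.any():
        raise TableSchemaError(f"{int(bad.sum())} rows have non-positive or non-finite Cq")
    key = ["gene", "group", "bio_rep", "tech_rep"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        offenders = df.loc[dup, key].drop_duplicates().to_records(index=False).tolist()
        raise DuplicateRowError(f"duplicate (gene, group, bio_rep, tech_rep) rows: {offenders}")
    n_flagged = int(df["cq"].isna().sum())
    logger.info("Cq table: %d rows ingested, %d flagged missing Cq", len(df), n_flagged)
    df.attrs["n_rows"] = len(df)
    df.attrs["n_flagged_missing"] = n_flagged
    return df.reset_index(drop=True)


def read_dilution_table(path, column_map=None, dilution_factor: float = 10.0,
                        mode: str = "explicit_conc", dialect=None, sheet=None) -> pd.DataFrame:
    """Read a dilution-series table for standard-curve fitting.

    In ``step_index`` mode the file carries an integer dilution step (0 =
    undiluted) in the ``rel_conc`` column slot, and relative concentration is
    computed as ``dilution_factor ** -step``.  In ``explicit_conc`` mode the
    column already holds relative concentrations.
    """
    if mode not in ("explicit_conc", "step_index"):
        raise ValueError(f"mode must be 'explicit_conc' or 'step_index', got {mode!r}")
    raw = _read_any(path, dialect, sheet)
    col_key = "step" if mode == "step_index" else "rel_conc"
    df = _apply_column_map(raw, column_map, required=["gene", col_key, "cq"])
    if mode == "step_index":
        if dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1 in step_index mode")
        steps = pd.to_numeric(df["step"], errors="raise")
        if (steps < 0).any() or (steps % 1 != 0).any():
            raise TableSchemaError("dilution steps must be non-negative integers")
        df["rel_conc"] = float(dilution_factor) ** (-steps.astype(float))
    else:
        df["rel_conc"] = pd.to_numeric(df["rel_conc"], errors="raise")
    df["cq"] = pd.to_numeric(df["cq"], errors="raise")
    out = df[DILUTION_COLUMNS].copy()
    out.attrs["dilution_factor"] = float(dilution_factor)
    return validate_dilution_table(out)


def validate_dilution_table(df: pd.DataFrame) -> pd.DataFrame:
    attrs = dict(df.attrs)
    missing_cols = [c for c in DILUTION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TableSchemaError(f"dilution table missing columns: {missing_cols}")
    df = df[DILUTION_COLUMNS].copy()
    if (df["rel_conc"] <= 0).any():
        raise TableSchemaError("relative concentrations must be positive")
    for gene, sub in df.groupby("gene"):
        n_conc = sub["rel_conc"].nunique()
        if n_conc < 3:
            raise TableSchemaError(
                f"gene {gene!r} has only {n_conc} distinct concentrations; >= 3 required"
            )
    df.attrs.update(attrs)
    return df.reset_index(drop=True)


def read_concentration_table(path, column_map=None, dialect=None, sheet=None) -> pd.DataFrame:
    """Read RNA concentrations, one row per replicate measurement (ng/ul)."""
    raw = _read_any(path, dialect, sheet)
    df = _apply_column_map(raw, column_map, required=["sample", "conc"])
    df["conc"] = pd.to_numeric(df["conc"], errors="raise")
    out = df[CONC_COLUMNS].copy()
    return validate_concentration_table(out)


def validate_concentration_table(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in CONC_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TableSchemaError(f"concentration table missing columns: {missing_cols}")
    df = df[CONC_COLUMNS].copy()
    if (df["conc"] <= 0).any():
        raise TableSchemaError("RNA concentrations must be positive")
    return df.reset_index(drop=True)


# Serialization precision by column kind: volumes 2 dp, expression-like
# quantities 4 significant digits, p-values scientific with 3 significant digits.
_VOLUME_COLS = {"rna_vol", "water_vol", "total_vol", "avg_conc"}
_EXPR_COLS = {"rel_expr", "fold_change", "rq", "nf", "nrq", "nrq_scaled",
              "mean", "sd", "se", "delta_ct", "delta_delta_ct", "estimate"}
_PVALUE_COLS = {"p_value", "anova_p", "adj_p"}


def _format_value(col: str, value):
    if pd.isna(value):
        return ""
    if col in _PVALUE_COLS:
        return f"{value:.2e}"
    if col in _VOLUME_COLS or col.endswith("_ul"):
        return f"{value:.2f}"
    if col in _EXPR_COLS:
        return f"{value:.4g}"
    return value


def write_result_table(table: pd.DataFrame, path, dialect=None) -> None:
    """Write a result table with documented column order and fixed precision.

    Volumes are serialized with 2 decimal places, expression quantities with 4
    significant digits and p-values in scientific notation (3 s.f.).
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower().lstrip(".")
        dialect = {"tsv": "tsv", "xlsx": "xlsx"}.get(suffix, "csv")
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v, c=col: _format_value(c, v))
    if dialect == "csv":
        out.to_csv(path, index=False)
    elif dialect == "tsv":
        out.to_csv(path, sep="\t", index=False)
    elif dialect == "xlsx":
        out.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
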