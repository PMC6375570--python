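"""Breeding-table schema and delimited-file round trip.

The breeding table is the pipeline's central exchange format: one row per
sampled offspring, with identifiers, ages, telomere lengths (TL, bp) and
foster assignments.  Files are plain CSV (comma, UTF-8, header row, empty
string = missing).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SCHEMA_COLUMNS",
    "SchemaError",
    "validate_table",
    "read_table",
    "write_table",
]


class SchemaError(ValueError):
    """A breeding table violates the CSV schema."""


#: column name -> (pandas dtype, mandatory)
SCHEMA_COLUMNS: dict[str, tuple[str, bool]] = {
    "offspring_id": ("string", True),
    "year": ("int64", True),
    "nest_id": ("string", True),
    "gel_id": ("string", True),
    "offspring_age_d": ("int64", True),
    "offspring_tl_bp": ("float64", True),
    "father_id": ("string", True),
    "mother_id": ("string", True),
    "foster_father_id": ("string", True),
    "foster_mother_id": ("string", True),
    "father_age_y": ("float64", True),
    "mother_age_y": ("float64", True),
    "foster_father_age_y": ("float64", True),
    "foster_mother_age_y": ("float64", True),
    "father_tl_bp": ("float64", False),
    "mother_tl_bp": ("float64", False),
    "cross_fostered": ("bool", True),
}

_NUMERIC = {c for c, (dt, _) in SCHEMA_COLUMNS.items() if dt in ("int64", "float64")}


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a breeding table against the schema.

    Returns the table with canonical column dtypes.  Raises
    :class:`SchemaError` naming the offending column (and row where
    applicable) on the first violation found.
    """
    for col, (_, mandatory) in SCHEMA_COLUMNS.items():
        if mandatory and col not in table.columns:
            raise SchemaError(f"missing mandatory column {col!r}")

    out = table.copy()
    for col in _NUMERIC:
        if col not in out.columns:
            continue
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(f"non-numeric value in column {col!r} at row {row}")
        out[col] = coerced

    dup = out["offspring_id"].duplicated()
    if dup.any():
        row = int(dup.idxmax())
        raise SchemaError(
            f"duplicate offspring_id {out['offspring_id'].iloc[row]!r} at row {row}"
        )

    if len(out):
        tl = out["offspring_tl_bp"]
        if tl.isna().any() or (tl <= 0).any():
            row = int((tl.isna() | (tl <= 0)).idxmax())
            raise SchemaError(f"offspring_tl_bp must be positive at row {row}")
        age = out["offspring_age_d"]
        if (~age.isin([2, 3, 4])).any():
            row = int((~age.isin([2, 3, 4])).idxmax())
            raise SchemaError(f"offspring_age_d outside 2-4 days at row {row}")

    for col, (dtype, mandatory) in SCHEMA_COLUMNS.items():
        if col not in out.columns:
            continue
        if dtype == "bool":
            out[col] = out[col].astype(bool)
        elif dtype == "string":
            out[col] = out[col].astype("string")
        elif len(out) and not out[col].isna().any():
            out[col] = out[col].astype(dtype)
    return out


def write_table(table: pd.DataFrame, path) -> None:
    """Write a breeding table to CSV (validated first)."""
    validate_table(table).to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    """Read and validate a breeding-table CSV."""
    df = pd.read_csv(
        path,
        keep_default_na=False,
        na_values=[""],
        dtype={c: "string" for c, (dt, _) in SCHEMA_COLUMNS.items() if dt == "string"},
    )
    if "cross_fostered" in df.columns and len(df):
        df["cross_fostered"] = (
            df["cross_fostered"].astype("string").str.lower().isin(["true", "1"])
        )
    elif "cross_fostered" in df.columns:
        df["cross_fostered"] = df["cross_fostered"].astype(bool)
    return validate_table(df)
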