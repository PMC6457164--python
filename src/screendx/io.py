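"""Canonical cohort CSV reading/writing with schema validation.

One row per woman; missing values are encoded as empty fields (never "NA",
which is ambiguous under numeric parsing).  Unknown extra columns are
preserved on read but ignored by the validators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import SchemaError

ITEM_COLUMNS = [f"item_{j}" for j in range(1, 11)]

CANONICAL_COLUMNS = (
    ["id", "age", "ethnicity", "income", "education", "employment",
     "interpreter", "mode", "dx_depression", "dx_anxiety", "dx_any",
     "screen_q1", "screen_q2", "help_q"]
    + ITEM_COLUMNS
    + ["consented", "stratum", "module_observed_depression", "module_observed_any"]
)

_INT_COLUMNS = ["interpreter", "dx_depression", "dx_anxiety", "dx_any",
                "screen_q1", "screen_q2", "consented",
                "module_observed_depression", "module_observed_any"]
_FLOAT_COLUMNS = ["age", "help_q"] + ITEM_COLUMNS
_STR_COLUMNS = ["id", "ethnicity", "income", "education", "employment",
                "mode", "stratum"]


#: numeric columns the sampling/weighting stages append to the canonical set
OPTIONAL_NUMERIC_COLUMNS = ["invited", "interviewed", "design_weight",
                            "analysis_weight", "latent_score"]


def write_cohort_csv(records: pd.DataFrame, path,
                     extra_columns: list[str] | None = None) -> None:
    """Write the canonical columns (exactly, in order); NaN -> empty field.

    ``extra_columns`` (e.g. invited/interviewed/design_weight after the
    sampling stage) are appended after the canonical block.
    """
    missing = [c for c in CANONICAL_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"records lack canonical columns: {missing}")
    cols = CANONICAL_COLUMNS + [c for c in (extra_columns or [])
                                if c in records.columns]
    out = records[cols].copy()
    for col in ["help_q"] + ITEM_COLUMNS:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False, na_rep="")


def _fail(column: str, row, message: str):
    raise SchemaError(f"column {column!r}, row {row}: {message}")


def validate_cohort(records: pd.DataFrame) -> None:
    """Check the canonical schema and the record-level invariants."""
    for col in CANONICAL_COLUMNS:
        if col not in records.columns:
            raise SchemaError(f"missing required column {col!r}")
    if len(records) == 0:
        raise SchemaError("cohort has no rows")
    if records["id"].duplicated().any():
        row = records.index[records["id"].duplicated()][0]
        _fail("id", row, "duplicate identifier")
    for col in _INT_COLUMNS:
        bad = ~records[col].isin([0, 1])
        if bad.any():
            _fail(col, records.index[bad][0], "must be 0 or 1")
    bad = ~records["stratum"].isin(["positive", "negative"])
    if bad.any():
        _fail("stratum", records.index[bad][0], "must be positive|negative")
    either = (records["screen_q1"] == 1) | (records["screen_q2"] == 1)
    mismatch = (records["stratum"] == "positive") != either
    if mismatch.any():
        _fail("stratum", records.index[mismatch][0],
              "stratum must equal positive iff screen_q1 or screen_q2 is yes")
    bad = records["help_q"].notna() & ~either
    if bad.any():
        _fail("help_q", records.index[bad][0],
              "help question must be missing for screen-negative women")
    for col in ITEM_COLUMNS:
        vals = records[col]
        bad = vals.notna() & ~vals.isin([0, 1, 2, 3])
        if bad.any():
            _fail(col, records.index[bad][0], "item score must be in 0..3")
    bad = records["age"].isna() | (records["age"] < 0)
    if bad.any():
        _fail("age", records.index[bad][0], "age must be a nonnegative number")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read, type and validate a canonical cohort CSV.

    Recomputes ``total_score`` (sum of items when all ten are observed).
    An empty file is a schema error, not an empty collection.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    df = df.mask(df == "")
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in _INT_COLUMNS:
        try:
            df[col] = df[col].astype(float).astype("Int64").astype(int)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r}: non-integer value ({exc})") from exc
    for col in _FLOAT_COLUMNS:
        try:
            df[col] = df[col].astype(float)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r}: non-numeric value ({exc})") from exc
    for col in OPTIONAL_NUMERIC_COLUMNS:
        if col in df.columns:
            try:
                df[col] = df[col].astype(float)
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"column {col!r}: non-numeric value ({exc})") from exc
    validate_cohort(df)
    items = df[ITEM_COLUMNS]
    df["total_score"] = np.where(items.notna().all(axis=1),
                                 items.sum(axis=1), np.nan)
    return df
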