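"""Ingestion of raw survey records and derived clinical measures.

A cohort is a :class:`pandas.DataFrame` with one row per subject and the
canonical columns in :data:`RAW_COLUMNS` (units documented there). Missing
values are ``NaN`` (read from empty fields or the literal ``NA``).

This module provides the subject-level arithmetic (BMI, Friedewald LDL,
HOMA-IR) both as scalar functions with explicit error contracts and as a
vectorized :func:`derive_measures` step, plus the cohort exclusion filter
used before any analysis: pregnant women, records with an incomplete lab
panel (triglycerides, HDL, total cholesterol, fasting glucose, fasting
insulin), and subjects outside the 25-64 year age range are removed, each
with a single reason code.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    EmptyCohortError,
    InvalidMeasurementError,
    MissingLabError,
    NamedColumnError,
)

#: Canonical raw columns, in file order. Units: age years; weight kg; height m;
#: waist cm; sbp/dbp mmHg; fpg, tg, hdl, tc, ldl_direct mg/dL; insulin uU/mL
#: (numerically identical to mU/L, the scale the HOMA constant 405 assumes).
RAW_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "weight",
    "height",
    "waist",
    "sbp",
    "dbp",
    "fpg",
    "insulin",
    "tg",
    "hdl",
    "tc",
    "ldl_direct",
    "diabetes_history",
    "antihypertensive_med",
    "pregnant",
]

#: Lab panel whose completeness is required for a record to be analyzable.
LAB_COLUMNS = ["tg", "hdl", "tc", "fpg", "insulin"]

#: Columns added by :func:`derive_measures`.
DERIVED_COLUMNS = ["bmi", "ldl", "homa_ir"]

BOOL_COLUMNS = ["diabetes_history", "antihypertensive_med", "pregnant"]

#: Inclusive age range of the survey population, years.
AGE_MIN, AGE_MAX = 25, 64

#: Triglyceride ceiling (mg/dL) for the Friedewald LDL estimate.
FRIEDEWALD_TG_MAX = 400.0

#: Denominator of the HOMA-IR score for insulin in uU/mL and glucose in mg/dL.
HOMA_DENOMINATOR = 405.0

_EXCLUSION_REASONS = ("pregnancy", "missing-lab", "age-range")


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def compute_bmi(weight: float, height: float) -> float:
    """Body-mass index: weight (kg) divided by height (m) squared.

    Raises
    ------
    InvalidMeasurementError
        If either input is missing or non-positive.
    """
    if _is_missing(weight) or _is_missing(height):
        raise InvalidMeasurementError("BMI requires weight and height")
    if weight <= 0 or height <= 0:
        raise InvalidMeasurementError(
            f"weight and height must be positive, got weight={weight}, height={height}"
        )
    return weight / (height * height)


def compute_homa_ir(insulin: float, glucose: float) -> float:
    """HOMA-IR: fasting insulin (uU/mL) x fasting glucose (mg/dL) / 405.

    Raises
    ------
    MissingLabError
        If either lab value is absent (such records are excluded upstream).
    InvalidMeasurementError
        If either value is negative.
    """
    if _is_missing(insulin) or _is_missing(glucose):
        raise MissingLabError("HOMA-IR requires fasting insulin and glucose")
    if insulin < 0 or glucose < 0:
        raise InvalidMeasurementError(
            f"insulin and glucose must be non-negative, got {insulin}, {glucose}"
        )
    return insulin * glucose / HOMA_DENOMINATOR


def compute_ldl(
    tc: float, hdl: float, tg: float, ldl_direct: float | None = None
) -> float:
    """LDL cholesterol in mg/dL.

    Friedewald estimate ``tc - hdl - tg/5`` when triglycerides are at or
    below 400 mg/dL; above that the formula is invalid and the directly
    measured value is returned instead. If triglycerides exceed 400 and no
    direct measurement exists, ``NaN`` is returned (the record is retained:
    LDL enters no metabolic-syndrome rule).

    Raises
    ------
    MissingLabError
        If tc, hdl, or tg is absent.
    """
    if _is_missing(tc) or _is_missing(hdl) or _is_missing(tg):
        raise MissingLabError("LDL requires total cholesterol, HDL and triglycerides")
    if tg <= FRIEDEWALD_TG_MAX:
        return tc - hdl - tg / 5.0
    if ldl_direct is None or _is_missing(ldl_direct):
        return math.nan
    return float(ldl_direct)


def derive_measures(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of *cohort* with ``bmi``, ``ldl`` and ``homa_ir`` columns.

    Vectorized counterpart of the scalar functions: rows whose inputs are
    missing (or non-positive, for BMI) get ``NaN`` in the derived column
    rather than raising, so derivation can run before or after exclusion
    filtering.
    """
    df = cohort.copy()
    w = df["weight"].to_numpy(dtype=float)
    h = df["height"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        bmi = np.where((w > 0) & (h > 0), w / (h * h), np.nan)
    df["bmi"] = bmi

    tc = df["tc"].to_numpy(dtype=float)
    hdl = df["hdl"].to_numpy(dtype=float)
    tg = df["tg"].to_numpy(dtype=float)
    ldl_direct = (
        df["ldl_direct"].to_numpy(dtype=float)
        if "ldl_direct" in df.columns
        else np.full(len(df), np.nan)
    )
    friedewald = tc - hdl - tg / 5.0
    df["ldl"] = np.where(tg <= FRIEDEWALD_TG_MAX, friedewald, ldl_direct)

    df["homa_ir"] = (
        df["insulin"].to_numpy(dtype=float)
        * df["fpg"].to_numpy(dtype=float)
        / HOMA_DENOMINATOR
    )
    return df


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the survey exclusion rules; return (retained, exclusion log).

    A record is retained iff it is non-pregnant, its full lab panel
    (:data:`LAB_COLUMNS`) is present, and 25 <= age <= 64 (both bounds
    inclusive). Each excluded record receives exactly one reason code, the
    first match in the fixed order pregnancy -> missing-lab -> age-range, so
    the log is deterministic. Idempotent by construction.

    Returns
    -------
    (retained, log)
        *retained* is a copy of the qualifying rows; *log* has columns
        ``subject_id`` and ``reason``.

    Raises
    ------
    EmptyCohortError
        If no record survives.
    """
    _require_columns(cohort, ["subject_id", "age", "pregnant"] + LAB_COLUMNS)
    pregnant = cohort["pregnant"].fillna(False).astype(bool).to_numpy()
    missing_lab = cohort[LAB_COLUMNS].isna().any(axis=1).to_numpy()
    age = cohort["age"].to_numpy(dtype=float)
    bad_age = ~((age >= AGE_MIN) & (age <= AGE_MAX))

    reason = np.full(len(cohort), "", dtype=object)
    reason[bad_age] = "age-range"
    reason[missing_lab] = "missing-lab"
    reason[pregnant] = "pregnancy"
    excluded = reason != ""

    retained = cohort.loc[~excluded].copy()
    if retained.empty:
        raise EmptyCohortError("all records excluded")
    log = pd.DataFrame(
        {
            "subject_id": cohort.loc[excluded, "subject_id"].to_numpy(),
            "reason": reason[excluded],
        }
    )
    return retained, log


# ---------------------------------------------------------------------------
# Delimited I/O


def _require_columns(df: pd.DataFrame, required: Iterable[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise NamedColumnError(f"input table lacks required columns: {missing}")


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_cohort(path, sep: str | None = None) -> pd.DataFrame:
    """Read a cohort table (comma default, tab accepted; '' or 'NA' missing).

    Boolean flag columns accept true/false, t/f, yes/no, 1/0 in any case.
    Validates that every raw column is present and that sex values are
    'male'/'female'.
    """
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(
        path, sep=sep, na_values=["NA", ""], keep_default_na=False, dtype={"subject_id": str}
    )
    _require_columns(df, [c for c in RAW_COLUMNS if c != "ldl_direct"])
    if "ldl_direct" not in df.columns:
        df["ldl_direct"] = np.nan
    for col in BOOL_COLUMNS:
        df[col] = _parse_bool(df[col], col)
    sex = df["sex"].astype(str).str.lower()
    bad = ~sex.isin(["male", "female"])
    if bad.any():
        raise InvalidMeasurementError(
            f"unrecognized sex values: {sorted(df.loc[bad, 'sex'].unique())}"
        )
    df["sex"] = sex
    return df


_TRUE = {"true", "t", "yes", "y", "1", "1.0"}
_FALSE = {"false", "f", "no", "n", "0", "0.0"}


def _parse_bool(s: pd.Series, name: str) -> pd.Series:
    def conv(v):
        if _is_missing(v):
            return False
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        text = str(v).strip().lower()
        if text in _TRUE:
            return True
        if text in _FALSE:
            return False
        raise InvalidMeasurementError(f"cannot parse boolean {name}={v!r}")

    return s.map(conv).astype(bool)


def write_cohort(cohort: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a cohort (or any subject table) as delimited text, NaN as 'NA'."""
    cohort.to_csv(path, sep=sep, index=False, na_rep="NA")
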