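"""Metabolic-syndrome classification under the ATPIII and IDF rule sets.

All classifiers are vectorized over a derived cohort DataFrame (see
``clinical_records``). Thresholds follow the printed criteria exactly:

ATPIII — MetS is three or more of: waist >= 102 cm (men) / >= 88 cm (women);
triglycerides >= 150 mg/dL; HDL < 40 (men) / < 50 (women) mg/dL; blood
pressure >= 130/85 mmHg; fasting glucose >= 100 mg/dL or diabetes.

IDF — mandatory central obesity, waist > 90 cm (strict, both sexes, the
Iranian population cut-off), plus any two of the four non-waist components
above.

Subjects on antihypertensive medication count as hypertensive under both
definitions. "Metabolically normal" subjects satisfy tg < 150,
sex-specific HDL >= 40/50, fpg < 100, sbp < 130, dbp < 85, tc <= 200 and
BMI <= 25, take no antihypertensive medication, and are not in the diabetic
stratum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import IncompleteRecordError, InvalidArgumentError

ATPIII_WAIST_MALE = 102.0  # cm, inclusive
ATPIII_WAIST_FEMALE = 88.0  # cm, inclusive
IDF_WAIST = 90.0  # cm, strict, both sexes
TG_HIGH = 150.0  # mg/dL, inclusive
HDL_LOW_MALE = 40.0  # mg/dL, strict <
HDL_LOW_FEMALE = 50.0  # mg/dL, strict <
SBP_HIGH = 130.0  # mmHg, inclusive
DBP_HIGH = 85.0  # mmHg, inclusive
FPG_HIGH = 100.0  # mg/dL, inclusive
FPG_DIABETES = 126.0  # mg/dL, inclusive (ADA)
TC_NORMAL_MAX = 200.0  # mg/dL, inclusive for "normal"
BMI_NORMAL_MAX = 25.0  # kg/m^2, inclusive for "normal"

COMPONENT_FLAGS = [
    "abdominal_obesity_atpiii",
    "central_obesity_idf",
    "high_tg",
    "low_hdl",
    "high_bp",
    "high_fpg",
]

DIABETES_RULES = ("history_only", "history_or_fpg126")


def _check_complete(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise IncompleteRecordError(f"{what}: cohort lacks columns {missing_cols}")
    na = df[cols].isna().any(axis=1)
    if na.to_numpy().any():
        bad = df.loc[na, "subject_id"].tolist() if "subject_id" in df else list(df.index[na])
        raise IncompleteRecordError(
            f"{what}: missing component inputs for records {bad[:5]}"
            + ("..." if len(bad) > 5 else "")
        )


def diabetes_stratum(
    cohort: pd.DataFrame, rule: str = "history_or_fpg126"
) -> pd.Series:
    """Assign each subject to the 'diabetic' or 'nondiabetic' stratum.

    ``history_only`` uses the interview flag alone; ``history_or_fpg126``
    (default) additionally calls fpg >= 126 mg/dL diabetic.
    """
    if rule not in DIABETES_RULES:
        raise InvalidArgumentError(f"unknown diabetes rule {rule!r}")
    _check_complete(cohort, ["diabetes_history"], "diabetes_stratum")
    diabetic = cohort["diabetes_history"].astype(bool).to_numpy()
    if rule == "history_or_fpg126":
        _check_complete(cohort, ["fpg"], "diabetes_stratum")
        diabetic = diabetic | (cohort["fpg"].to_numpy(dtype=float) >= FPG_DIABETES)
    return pd.Series(
        np.where(diabetic, "diabetic", "nondiabetic"), index=cohort.index, name="stratum"
    )


def atpiii_components(cohort: pd.DataFrame, diabetic: np.ndarray | pd.Series) -> pd.DataFrame:
    """Per-subject ATPIII component flags and their count.

    *diabetic* marks the diabetes stratum; it feeds the glucose component
    (fpg >= 100 "or diabetes"). Blood pressure counts if sbp >= 130 or
    dbp >= 85 or the subject takes antihypertensive medication.
    """
    cols = ["sex", "waist", "tg", "hdl", "sbp", "dbp", "fpg", "antihypertensive_med"]
    _check_complete(cohort, cols, "atpiii_components")
    diabetic = np.asarray(diabetic, dtype=bool)
    male = cohort["sex"].to_numpy() == "male"
    waist = cohort["waist"].to_numpy(dtype=float)
    out = pd.DataFrame(index=cohort.index)
    out["abdominal_obesity_atpiii"] = np.where(
        male, waist >= ATPIII_WAIST_MALE, waist >= ATPIII_WAIST_FEMALE
    )
    out["high_tg"] = cohort["tg"].to_numpy(dtype=float) >= TG_HIGH
    hdl = cohort["hdl"].to_numpy(dtype=float)
    out["low_hdl"] = np.where(male, hdl < HDL_LOW_MALE, hdl < HDL_LOW_FEMALE)
    out["high_bp"] = (
        (cohort["sbp"].to_numpy(dtype=float) >= SBP_HIGH)
        | (cohort["dbp"].to_numpy(dtype=float) >= DBP_HIGH)
        | cohort["antihypertensive_med"].astype(bool).to_numpy()
    )
    out["high_fpg"] = (cohort["fpg"].to_numpy(dtype=float) >= FPG_HIGH) | diabetic
    out["atpiii_count"] = out[
        ["abdominal_obesity_atpiii", "high_tg", "low_hdl", "high_bp", "high_fpg"]
    ].sum(axis=1)
    return out


def classify_atpiii(components: pd.DataFrame) -> pd.Series:
    """ATPIII MetS: three or more of the five components."""
    return (components["atpiii_count"] >= 3).rename("mets_atpiii")


def classify_idf(cohort: pd.DataFrame, components: pd.DataFrame) -> pd.Series:
    """IDF MetS: waist > 90 cm (mandatory) plus >= 2 of the other components."""
    _check_complete(cohort, ["waist"], "classify_idf")
    central = cohort["waist"].to_numpy(dtype=float) > IDF_WAIST
    secondary = components[["high_tg", "low_hdl", "high_bp", "high_fpg"]].sum(axis=1)
    return pd.Series(central & (secondary >= 2).to_numpy(), index=cohort.index, name="mets_idf")


def is_metabolically_normal(
    cohort: pd.DataFrame, diabetic: np.ndarray | pd.Series | None = None
) -> pd.Series:
    """Subjects without any metabolic abnormality.

    Requires tg < 150, HDL >= 40 (men) / >= 50 (women), fpg < 100,
    sbp < 130, dbp < 85, tc <= 200, BMI <= 25, no antihypertensive
    medication, and (when *diabetic* is given) nondiabetic stratum.
    """
    cols = ["sex", "tg", "hdl", "fpg", "sbp", "dbp", "tc", "bmi", "antihypertensive_med"]
    _check_complete(cohort, cols, "is_metabolically_normal")
    male = cohort["sex"].to_numpy() == "male"
    hdl = cohort["hdl"].to_numpy(dtype=float)
    normal = (
        (cohort["tg"].to_numpy(dtype=float) < TG_HIGH)
        & np.where(male, hdl >= HDL_LOW_MALE, hdl >= HDL_LOW_FEMALE)
        & (cohort["fpg"].to_numpy(dtype=float) < FPG_HIGH)
        & (cohort["sbp"].to_numpy(dtype=float) < SBP_HIGH)
        & (cohort["dbp"].to_numpy(dtype=float) < DBP_HIGH)
        & (cohort["tc"].to_numpy(dtype=float) <= TC_NORMAL_MAX)
        & (cohort["bmi"].to_numpy(dtype=float) <= BMI_NORMAL_MAX)
        & ~cohort["antihypertensive_med"].astype(bool).to_numpy()
    )
    if diabetic is not None:
        normal = normal & ~np.asarray(diabetic, dtype=bool)
    return pd.Series(normal, index=cohort.index, name="metabolically_normal")


def assess_cohort(
    cohort: pd.DataFrame, diabetes_rule: str = "history_or_fpg126"
) -> pd.DataFrame:
    """Full per-subject assessment table.

    Columns: subject_id, the six component flags, atpiii_count, mets_atpiii,
    mets_idf, metabolically_normal, stratum.
    """
    stratum = diabetes_stratum(cohort, diabetes_rule)
    diabetic = (stratum == "diabetic").to_numpy()
    comp = atpiii_components(cohort, diabetic)
    out = pd.DataFrame(index=cohort.index)
    if "subject_id" in cohort.columns:
        out["subject_id"] = cohort["subject_id"]
    out["central_obesity_idf"] = cohort["waist"].to_numpy(dtype=float) > IDF_WAIST
    for c in ["abdominal_obesity_atpiii", "high_tg", "low_hdl", "high_bp", "high_fpg", "atpiii_count"]:
        out[c] = comp[c]
    out["mets_atpiii"] = classify_atpiii(comp)
    out["mets_idf"] = classify_idf(cohort, comp)
    out["metabolically_normal"] = is_metabolically_normal(cohort, diabetic)
    out["stratum"] = stratum
    return out
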