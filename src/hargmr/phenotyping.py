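"""Rule-based classification of prevalent/incident cardiometabolic outcomes.

Converts measured traits into binary outcome flags using the harmonized
metabolic-syndrome component criteria plus obesity, high fasting insulin,
type 2 diabetes, coronary artery calcification (CAC) and high-risk carotid
phenotypes:

* abdominal obesity: waist circumference ≥102 cm (men) / ≥88 cm (women)
* hypertriglyceridemia: triglycerides >1.7 mmol/L
* low HDL: <1.0 mmol/L (men) / <1.3 mmol/L (women)
* high blood pressure: systolic ≥130 mmHg OR diastolic ≥85 mmHg OR treatment
* hyperglycaemia: fasting glucose ≥5.6 mmol/L or previously diagnosed T2DM
* obesity: BMI ≥30 kg/m²
* high insulin: fasting insulin above the sex-specific 90th percentile
  (operational cuts: ≥18.8 IU/L men, ≥15.2 IU/L women)
* T2DM: fasting glucose ≥7.0 mmol/L, HbA1c ≥6.5% (48 mmol/mol),
  glucose-lowering medication without reported type 1 diabetes, or a
  physician diagnosis
* CAC present: Agatston score ≥1 (absence = score of exactly 0)
* high-risk IMT / low distensibility: age- and sex-specific ≥90th / ≤10th
  percentile

Missing required inputs always yield missing flags (pandas NA), never False.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PercentileReference",
    "classify_record",
    "high_insulin_reference",
    "percentile_reference",
    "incident_risk_set",
    "OPERATIONAL_INSULIN_CUTS",
    "FLAG_COLUMNS",
]

FLAG_COLUMNS = [
    "abdominal_obesity",
    "hypertriglyceridemia",
    "low_hdl",
    "high_bp",
    "hyperglycaemia",
    "obesity",
    "high_insulin",
    "t2dm",
    "cac_present",
    "high_risk_imt",
    "low_distensibility",
]


@dataclass(frozen=True)
class PercentileReference:
    """A stratum-specific percentile cut for one variable.

    ``comparison`` is the operator applied as ``value <op> cut`` to flag a
    participant; ``quantile_rule`` records how the cut was computed (default
    Hyndman–Fan type 7, numpy's ``linear`` interpolation) so alternative
    definitions remain switchable.
    """

    variable: str
    stratum: str
    percentile: float
    cut: float
    comparison: str = ">"
    quantile_rule: str = "linear"

    def applies(self, values) -> "pd.Series":
        values = pd.Series(values, dtype="Float64")
        ops = {
            ">": values > self.cut,
            ">=": values >= self.cut,
            "<": values < self.cut,
            "<=": values <= self.cut,
        }
        if self.comparison not in ops:
            raise ValueError(f"unknown comparison {self.comparison!r}")
        return ops[self.comparison].astype("boolean")


#: Fixed operational insulin cuts (IU/L), quoted inclusive (≥).
OPERATIONAL_INSULIN_CUTS = {
    "male": PercentileReference("insulin", "male", 90.0, 18.8, ">="),
    "female": PercentileReference("insulin", "female", 90.0, 15.2, ">="),
}


def high_insulin_reference(
    insulin: pd.Series, sex: pd.Series, percentile: float = 90.0
) -> dict[str, PercentileReference]:
    """Sex-specific percentile cuts for the high-insulin flag.

    The flag rule is strictly greater than the cut (being *in* the top
    decile). Requires at least 10 non-missing values per sex stratum.
    """
    refs = {}
    sex = pd.Series(sex).astype(str)
    for stratum in ("male", "female"):
        vals = pd.Series(insulin)[sex == stratum].dropna()
        if len(vals) == 0:
            raise ValueError(f"empty insulin stratum: {stratum}")
        if len(vals) < 10:
            raise ValueError(
                f"need ≥10 non-missing insulin values for {stratum}, got {len(vals)}"
            )
        cut = float(np.quantile(vals.to_numpy(dtype=float), percentile / 100.0))
        refs[stratum] = PercentileReference("insulin", stratum, percentile, cut, ">")
    return refs


def percentile_reference(
    values: pd.Series,
    sex: pd.Series,
    age: pd.Series,
    variable: str,
    percentile: float,
    comparison: str,
    age_band_years: int = 3,
) -> dict[tuple[str, int], PercentileReference]:
    """Age-band × sex percentile cuts (for IMT / distensibility).

    Age bands are half-open ``age_band_years``-wide bins anchored at the
    minimum observed age; the key is ``(sex, band_index)``.
    """
    df = pd.DataFrame({"v": values, "sex": sex.astype(str), "age": age}).dropna()
    if df.empty:
        raise ValueError(f"no data to build percentile reference for {variable}")
    base = float(df["age"].min())
    df["band"] = ((df["age"] - base) // age_band_years).astype(int)
    refs = {}
    for (s, band), grp in df.groupby(["sex", "band"]):
        cut = float(np.quantile(grp["v"].to_numpy(dtype=float), percentile / 100.0))
        refs[(s, int(band))] = PercentileReference(
            variable, f"{s}/band{band}", percentile, cut, comparison
        )
    refs["_age_base"] = base
    refs["_age_band_years"] = age_band_years
    return refs


def _require(df: pd.DataFrame, col: str) -> pd.Series:
    if col in df.columns:
        return pd.Series(df[col], dtype="Float64")
    return pd.Series(pd.NA, index=df.index, dtype="Float64")


def _bool_col(df: pd.DataFrame, col: str) -> pd.Series:
    if col in df.columns:
        return pd.Series(df[col]).astype("boolean")
    return pd.Series(pd.NA, index=df.index, dtype="boolean")


def _by_sex(sex: pd.Series, male_rule: pd.Series, female_rule: pd.Series) -> pd.Series:
    return male_rule.where(sex == "male", female_rule).astype("boolean")


def _kleene_any(criteria: list[pd.Series], index) -> pd.Series:
    if not criteria:
        return pd.Series(pd.NA, index=index, dtype="boolean")
    out = criteria[0]
    for c in criteria[1:]:
        out = out | c
    return out.astype("boolean")


def classify_record(
    records: pd.DataFrame,
    insulin_refs: dict[str, PercentileReference] | None = None,
    imt_refs: dict | None = None,
    dist_refs: dict | None = None,
) -> pd.DataFrame:
    """Classify one or more participant records into outcome flags.

    ``records`` has one row per participant with trait columns in clinical
    units (waist cm, lipids and glucose mmol/L, BP mmHg, BMI kg/m²,
    insulin IU/L, HbA1c %) plus ``sex`` and optional treatment/diagnosis
    booleans (``bp_treatment``, ``glucose_med``, ``type1_diabetes``,
    ``t2dm_dx``) and ``agatston``/``imt``/``distensibility``.

    Returns a DataFrame of nullable-boolean flag columns aligned to the
    input index; a flag is NA wherever its required inputs are missing.
    BP treatment alone (measured BP missing) suffices for the BP flag.
    """
    if "sex" not in records.columns:
        raise ValueError("records must include a 'sex' column")
    sex = records["sex"].astype(str)
    unknown = ~sex.isin(["male", "female"])
    if unknown.any():
        raise ValueError(f"unknown sex values: {sorted(sex[unknown].unique())}")

    for col in ("tg", "hdl", "glucose", "insulin", "crp", "harg"):
        if col in records.columns and (pd.Series(records[col]) < 0).any():
            raise ValueError(f"negative concentrations in column {col!r}")

    flags = pd.DataFrame(index=records.index)
    waist = _require(records, "waist")
    flags["abdominal_obesity"] = _by_sex(sex, waist >= 102, waist >= 88)

    tg = _require(records, "tg")
    flags["hypertriglyceridemia"] = (tg > 1.7).astype("boolean")

    hdl = _require(records, "hdl")
    flags["low_hdl"] = _by_sex(sex, hdl < 1.0, hdl < 1.3)

    # Multi-criterion flags use three-valued (Kleene) OR over the criteria
    # whose input columns are present: NA|True=True, NA|False=NA, so
    # treatment alone suffices when BP readings are missing, while a flag is
    # never False just because an input was unobserved.
    sbp, dbp = _require(records, "sbp"), _require(records, "dbp")
    bp_criteria = [(sbp >= 130).astype("boolean"), (dbp >= 85).astype("boolean")]
    if "bp_treatment" in records.columns:
        bp_criteria.append(_bool_col(records, "bp_treatment"))
    flags["high_bp"] = _kleene_any(bp_criteria, records.index)

    glucose = _require(records, "glucose")
    hg_criteria = [(glucose >= 5.6).astype("boolean")]
    if "t2dm_dx" in records.columns:
        hg_criteria.append(_bool_col(records, "t2dm_dx"))
    flags["hyperglycaemia"] = _kleene_any(hg_criteria, records.index)

    bmi = _require(records, "bmi")
    flags["obesity"] = (bmi >= 30).astype("boolean")

    insulin = _require(records, "insulin")
    refs = insulin_refs or OPERATIONAL_INSULIN_CUTS
    flags["high_insulin"] = _by_sex(
        sex, refs["male"].applies(insulin), refs["female"].applies(insulin)
    )

    hba1c = _require(records, "hba1c")
    t2_criteria = []
    if "glucose" in records.columns:
        t2_criteria.append((glucose >= 7.0).astype("boolean"))
    if "hba1c" in records.columns:
        t2_criteria.append((hba1c >= 6.5).astype("boolean"))
    if "glucose_med" in records.columns:
        med = _bool_col(records, "glucose_med")
        type1 = _bool_col(records, "type1_diabetes").fillna(False)
        t2_criteria.append((med & ~type1).astype("boolean"))
    if "t2dm_dx" in records.columns:
        t2_criteria.append(_bool_col(records, "t2dm_dx"))
    flags["t2dm"] = _kleene_any(t2_criteria, records.index)

    agatston = _require(records, "agatston")
    flags["cac_present"] = (agatston >= 1).astype("boolean")

    flags["high_risk_imt"] = _percentile_flag(records, sex, "imt", imt_refs)
    flags["low_distensibility"] = _percentile_flag(
        records, sex, "distensibility", dist_refs
    )
    return flags


def _percentile_flag(records, sex, variable, refs):
    if refs is None or variable not in records.columns:
        return pd.Series(pd.NA, index=records.index, dtype="boolean")
    base = refs["_age_base"]
    width = refs["_age_band_years"]
    age = _require(records, "age")
    values = _require(records, variable)
    out = pd.Series(pd.NA, index=records.index, dtype="boolean")
    band = ((age - base) // width).astype("Float64")
    for i in records.index:
        if pd.isna(values[i]) or pd.isna(band[i]):
            continue
        key = (sex[i], int(band[i]))
        if key not in refs:  # clamp out-of-range ages to the nearest band
            bands = [b for (s, b) in refs if s == sex[i] and isinstance(b, int)]
            if not bands:
                continue
            key = (sex[i], min(bands, key=lambda b: abs(b - int(band[i]))))
        out[i] = bool(refs[key].applies(pd.Series([values[i]])).iloc[0])
    return out


def incident_risk_set(
    baseline_flags: pd.DataFrame, followup_flags: pd.DataFrame
) -> dict[str, dict[str, pd.Index]]:
    """Per-outcome at-risk and incident participant sets.

    A participant is at risk for an outcome when the baseline flag is
    observed False and the follow-up flag is observed (prevalent cases are
    excluded; unobservable follow-ups contribute nothing). Incident cases
    are the at-risk participants whose follow-up flag is True.
    """
    if not baseline_flags.index.equals(followup_flags.index):
        raise ValueError("baseline and follow-up flag tables have mismatched ids")
    result = {}
    common = [c for c in baseline_flags.columns if c in followup_flags.columns]
    for outcome in common:
        base = baseline_flags[outcome].astype("boolean")
        fup = followup_flags[outcome].astype("boolean")
        at_risk = (base == False) & fup.notna()  # noqa: E712  (NA-aware)
        incident = at_risk & (fup == True)  # noqa: E712
        result[outcome] = {
            "at_risk": baseline_flags.index[at_risk.fillna(False)],
            "incident": baseline_flags.index[incident.fillna(False)],
        }
    return result
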