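"""Incident-outcome logistic models for baseline hArg.

Fits sex-stratified logistic regressions of incident cardiometabolic
outcomes (6/7/10-year horizons) on SD-scaled ln-hArg at baseline, in three
nested adjustment tiers:

* Model 1 — unadjusted;
* Model 2 — adjusted for the baseline cardiometabolic risk factors (age,
  LDL, HDL, ln triglycerides, systolic and diastolic BP, ln CRP, glucose,
  ln insulin, BMI, waist circumference, daily smoking, family history of
  CAD);
* Model 3 — further adjusted for ln SHBG, plus oral-contraceptive use in
  the women stratum.

Skewed covariates (triglycerides, CRP, insulin, SHBG) enter log-transformed.
Prevalent cases are excluded upstream via the incident risk set; odds ratios
are per 1-SD increment in ln-hArg with Wald 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["IncidentModelSpec", "IncidentResult", "fit_incident_model", "run_model_grid"]

MODEL2_COVARIATES = [
    "age",
    "ldl",
    "hdl",
    "ln_tg",
    "sbp",
    "dbp",
    "ln_crp",
    "glucose",
    "ln_insulin",
    "bmi",
    "waist",
    "smoker",
    "family_history",
]

_LOG_COVARIATES = {"ln_tg": "tg", "ln_crp": "crp", "ln_insulin": "insulin", "ln_shbg": "shbg"}


@dataclass(frozen=True)
class IncidentModelSpec:
    """One cell of the outcome × adjustment-tier × sex grid."""

    outcome: str
    horizon: int = 10
    tier: int = 1
    stratum: str = "male"

    def covariates(self) -> list[str]:
        if self.tier == 1:
            return []
        cov = list(MODEL2_COVARIATES)
        if self.tier >= 3:
            cov.append("ln_shbg")
            if self.stratum == "female":
                cov.append("oc_use")
        return cov


@dataclass
class IncidentResult:
    """Odds ratio per 1-SD ln-hArg for one incident outcome model."""

    outcome: str
    stratum: str
    tier: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n_at_risk: int
    n_incident: int
    converged: bool
    separation_flag: bool = False


def _design_frame(cohort: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=cohort.index)
    for cov in covariates:
        if cov in _LOG_COVARIATES:
            X[cov] = np.log(cohort[_LOG_COVARIATES[cov]].astype(float))
        else:
            X[cov] = cohort[cov].astype(float)
    return X


def fit_incident_model(
    cohort: pd.DataFrame,
    spec: IncidentModelSpec,
    outcome_series: pd.Series | None = None,
    exposure: str = "ln_harg",
) -> IncidentResult:
    """Fit one incident-outcome logistic model.

    ``cohort`` must already be restricted to the at-risk set for the outcome
    (baseline-prevalent cases excluded, follow-up observed). The outcome is
    read from ``outcome_series`` or the column ``inc_<outcome>``; the
    exposure is ln-hArg scaled to unit SD within the supplied rows.

    Raises on zero incident cases; quasi-complete separation is flagged via
    convergence diagnostics and inflated standard errors.
    """
    if spec.stratum in ("male", "female"):
        rows = cohort[cohort["sex"] == spec.stratum]
    else:
        rows = cohort
    y = (
        outcome_series.loc[rows.index]
        if outcome_series is not None
        else rows[f"inc_{spec.outcome}"]
    )
    y = pd.Series(y).astype("boolean")
    ok = y.notna()
    rows, y = rows[ok.to_numpy()], y[ok.to_numpy()].astype(bool)

    n_at_risk = len(rows)
    n_incident = int(y.sum())
    if n_incident == 0:
        raise ValueError(f"no events for outcome {spec.outcome!r} in {spec.stratum}")
    if n_incident == n_at_risk:
        raise ValueError(f"all at-risk participants had the event: {spec.outcome!r}")

    ln_h = rows[exposure].to_numpy(dtype=float)
    z = (ln_h - ln_h.mean()) / ln_h.std(ddof=1)
    X = _design_frame(rows, spec.covariates())
    X.insert(0, "z_ln_harg", z)
    design = sm.add_constant(X.reset_index(drop=True), has_constant="add")

    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        warnings.warn(
            f"collinear covariates in {spec.outcome}/{spec.stratum} tier {spec.tier}"
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y.to_numpy(dtype=float), design).fit(disp=0, maxiter=200)

    coef = fit.params["z_ln_harg"]
    se = fit.bse["z_ln_harg"]
    separation = bool(not fit.mle_retvals.get("converged", True) or se > 50)
    ci = fit.conf_int().loc["z_ln_harg"]
    return IncidentResult(
        outcome=spec.outcome,
        stratum=spec.stratum,
        tier=spec.tier,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        p=float(fit.pvalues["z_ln_harg"]),
        n_at_risk=n_at_risk,
        n_incident=n_incident,
        converged=bool(fit.mle_retvals.get("converged", True)),
        separation_flag=separation,
    )


def run_model_grid(
    cohort: pd.DataFrame,
    outcomes: list[str] | dict[str, int],
    tiers: tuple[int, ...] = (1, 2, 3),
    strata: tuple[str, ...] = ("male", "female"),
) -> pd.DataFrame:
    """Fit the full outcome × tier × sex grid; failures become annotated rows.

    ``outcomes`` may map outcome name → follow-up horizon (years); a plain
    list uses the 10-year horizon. Returns a forest-table-ready long format
    with event counts per cell; cells whose fit fails carry NaN estimates
    and the error message, and never abort the rest of the grid.
    """
    horizons = outcomes if isinstance(outcomes, dict) else {o: 10 for o in outcomes}
    rows = []
    for outcome, horizon in horizons.items():
        for stratum in strata:
            for tier in tiers:
                spec = IncidentModelSpec(outcome, horizon, tier, stratum)
                try:
                    res = fit_incident_model(cohort, spec)
                    rows.append(
                        {
                            "outcome": outcome,
                            "horizon": horizon,
                            "stratum": stratum,
                            "tier": tier,
                            "odds_ratio": res.odds_ratio,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "p": res.p,
                            "n_at_risk": res.n_at_risk,
                            "n_incident": res.n_incident,
                            "error": "",
                        }
                    )
                except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
                    rows.append(
                        {
                            "outcome": outcome,
                            "horizon": horizon,
                            "stratum": stratum,
                            "tier": tier,
                            "odds_ratio": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "p": np.nan,
                            "n_at_risk": 0,
                            "n_incident": 0,
                            "error": str(exc),
                        }
                    )
    return pd.DataFrame(rows)
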