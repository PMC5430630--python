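"""Cross-sectional metabolome-wide association analysis of hArg.

Pipeline: metabolite preparation (zero replacement → natural log → SD
scaling, optionally within sex), an effective-number-of-tests multiple-
testing threshold from the principal-component spectrum of the prepared
matrix, the sex-stratified metabolome-wide linear-regression scan with
covariate adjustment, Z-tests for sex differences in the association
estimates, hArg×BMI interaction models, and bidirectional stepwise-AIC
selection of clinical hArg determinants.

Association magnitudes are in SD units of metabolite concentration per 1-SD
increment in ln-hArg, so estimates are comparable across metabolites and
invariant to the raw measurement units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "prepare_metabolites",
    "effective_test_threshold",
    "metabolome_scan",
    "sex_difference_z",
    "bmi_interaction",
    "stepwise_aic",
    "StepwiseResult",
]


def _scale(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero variance after centring; cannot scale")
    return (x - x.mean()) / sd


def prepare_metabolites(
    matrix: pd.DataFrame,
    sex: pd.Series | None = None,
    per_sex: bool = False,
) -> pd.DataFrame:
    """Zero-replace, log-transform and SD-scale a raw metabolite matrix.

    Zeros in each column are replaced by half the column's minimum positive
    value (a detection-limit estimate) before taking natural logs; columns
    are then centred and scaled to unit SD, within sex strata when
    ``per_sex`` is set. Negative concentrations or all-zero columns raise.
    """
    if (matrix < 0).any().any():
        bad = matrix.columns[(matrix < 0).any()].tolist()
        raise ValueError(f"negative concentrations in columns: {bad}")
    if per_sex and sex is None:
        raise ValueError("per_sex scaling requires a sex vector")

    out = matrix.astype(float).copy()
    for col in out.columns:
        v = out[col].to_numpy()
        positive = v[v > 0]
        if positive.size == 0:
            raise ValueError(f"column {col!r} is entirely zero; no positive minimum")
        v = np.where(v == 0, positive.min() / 2.0, v)
        out[col] = np.log(v)

    if per_sex:
        sex = pd.Series(sex).reset_index(drop=True)
        for stratum in sex.unique():
            idx = out.index[sex.to_numpy() == stratum]
            out.loc[idx] = out.loc[idx].apply(lambda c: _scale(c.to_numpy()), axis=0)
    else:
        out = out.apply(lambda c: _scale(c.to_numpy()), axis=0)

    out.attrs["transform"] = "ln-SD-scaled"
    out.attrs["scaling_stratum"] = "per-sex" if per_sex else "pooled"
    return out


def effective_test_threshold(
    matrix: pd.DataFrame,
    variance_target: float = 0.95,
    alpha: float = 0.05,
) -> tuple[int, float]:
    """Effective number of independent tests and the per-test threshold.

    k is the smallest number of principal components of the column
    correlation matrix whose cumulative explained variance reaches
    ``variance_target``; the Bonferroni-style threshold is ``alpha / k``.
    With 25 independent blocks of perfectly duplicated columns this yields
    k = 25 and a threshold of 0.05/25 = 0.002.
    """
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    if matrix.shape[1] < 1:
        raise ValueError("matrix must have at least one column")
    x = matrix.to_numpy(dtype=float)
    if matrix.shape[1] == 1:
        return 1, alpha
    corr = np.corrcoef(x, rowvar=False)
    eigvals = np.linalg.eigvalsh(corr)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    cum = np.cumsum(eigvals) / eigvals.sum()
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    return k, alpha / k


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient design; check covariates for collinearity: "
            f"{list(X.columns)}"
        )
    return sm.OLS(y, design).fit()


def _z_scale_harg(ln_harg: np.ndarray) -> np.ndarray:
    return _scale(np.asarray(ln_harg, dtype=float))


def metabolome_scan(
    ln_harg: pd.Series,
    matrix: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    sex: pd.Series | None = None,
    stratify_by_sex: bool = True,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Sex-stratified linear-regression scan of every metabolite on hArg.

    Each prepared metabolite column is regressed on SD-scaled ln-hArg plus
    the supplied covariates, separately per sex stratum (or pooled). Returns
    a long-format table (metabolite, stratum, beta, se, p, n, significant)
    with p-values from the t distribution on the residual df.
    """
    if stratify_by_sex and sex is None:
        raise ValueError("stratified scan requires a sex vector")
    strata = (
        [("all", np.ones(len(matrix), dtype=bool))]
        if not stratify_by_sex
        else [(s, (pd.Series(sex).to_numpy() == s)) for s in ("male", "female")]
    )
    rows = []
    for stratum, mask in strata:
        z = _z_scale_harg(pd.Series(ln_harg).to_numpy()[mask])
        cov = (
            covariates.loc[mask].reset_index(drop=True)
            if covariates is not None
            else pd.DataFrame(index=range(mask.sum()))
        )
        for met in matrix.columns:
            y = matrix[met].to_numpy(dtype=float)[mask]
            X = cov.copy()
            X.insert(0, "z_ln_harg", z)
            fit = _fit_ols(y, X)
            beta = fit.params["z_ln_harg"]
            se = fit.bse["z_ln_harg"]
            p = fit.pvalues["z_ln_harg"]
            rows.append(
                {
                    "metabolite": met,
                    "stratum": stratum,
                    "beta": beta,
                    "se": se,
                    "p": p,
                    "n": int(mask.sum()),
                    "significant": bool(p < threshold) if threshold else pd.NA,
                }
            )
    return pd.DataFrame(rows)


def sex_difference_z(
    beta_m: float, se_m: float, beta_f: float, se_f: float
) -> tuple[float, float]:
    """Z-statistic for a male-female difference in association estimates.

    Z = (β_m − β_f) / sqrt(SE_m² + SE_f²) with a two-sided normal p-value.
    """
    if se_m <= 0 or se_f <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_m - beta_f) / np.hypot(se_m, se_f)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def bmi_interaction(
    ln_harg: pd.Series,
    metabolite: pd.Series,
    bmi: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> dict[str, float]:
    """hArg×BMI interaction on one prepared metabolite within one stratum.

    Adds the product of SD-scaled ln-hArg and BMI to the adjusted linear
    model and reports the interaction coefficient, SE and p-value. The
    coefficient is invariant to centring BMI (only main effects shift).
    """
    z = _z_scale_harg(pd.Series(ln_harg).to_numpy())
    bmi = pd.Series(bmi).to_numpy(dtype=float)
    X = covariates.copy() if covariates is not None else pd.DataFrame(index=range(len(z)))
    X = X.reset_index(drop=True)
    X.insert(0, "z_ln_harg", z)
    if "bmi" not in X.columns:
        X["bmi"] = bmi
    X["harg_x_bmi"] = z * bmi
    fit = _fit_ols(pd.Series(metabolite).to_numpy(dtype=float), X)
    return {
        "beta": float(fit.params["harg_x_bmi"]),
        "se": float(fit.bse["harg_x_bmi"]),
        "p": float(fit.pvalues["harg_x_bmi"]),
        "n": int(len(z)),
    }


@dataclass
class StepwiseResult:
    """Selected linear model from the bidirectional AIC search."""

    terms: list[str]
    coefficients: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    r_squared: float
    aic: float
    n: int
    dropped_collinear: list[str] = field(default_factory=list)


def _aic_ols(y: np.ndarray, X: pd.DataFrame) -> tuple[float, "sm.regression.linear_model.RegressionResults"]:
    fit = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return fit.aic, fit


def stepwise_aic(
    response: pd.Series,
    candidates: pd.DataFrame,
    start: str = "full",
) -> StepwiseResult:
    """Bidirectional stepwise linear-model selection by AIC.

    Starting from the full model (or the intercept when ``start='intercept'``),
    every single-term addition and deletion is scored each round and the move
    with the lowest AIC is applied; the search stops when no move improves
    AIC. Ties are broken toward the smaller model. Perfectly collinear
    candidates are dropped with a warning before the search.
    """
    y = pd.Series(response).to_numpy(dtype=float)
    X = candidates.astype(float).reset_index(drop=True)

    dropped = []
    keep: list[str] = []
    for col in X.columns:  # greedy collinearity screen against retained set
        trial = keep + [col]
        mat = np.column_stack([np.ones(len(X))] + [X[c].to_numpy() for c in trial])
        if np.linalg.matrix_rank(mat) == len(trial) + 1:
            keep.append(col)
        else:
            dropped.append(col)
    if dropped:
        import warnings

        warnings.warn(f"dropping perfectly collinear candidates: {dropped}")
    X = X[keep]

    current = list(X.columns) if start == "full" else []
    current_aic, _ = _aic_ols(y, X[current])

    while len(X.columns) > 0:
        moves = []  # (aic, size, terms)
        for col in X.columns:
            if col in current:
                terms = [c for c in current if c != col]
            else:
                terms = current + [col]
            aic, _ = _aic_ols(y, X[terms])
            moves.append((aic, len(terms), terms))
        moves.sort(key=lambda m: (round(m[0], 10), m[1]))
        best_aic, best_size, best_terms = moves[0]
        tol = 1e-10
        if best_aic < current_aic - tol or (
            abs(best_aic - current_aic) <= tol and best_size < len(current)
        ):
            current, current_aic = best_terms, best_aic
        else:
            break

    aic, fit = _aic_ols(y, X[current])
    return StepwiseResult(
        terms=list(current),
        coefficients=fit.params,
        conf_int=fit.conf_int().rename(columns={0: "ci_low", 1: "ci_high"}),
        pvalues=fit.pvalues,
        r_squared=float(fit.rsquared),
        aic=float(aic),
        n=len(y),
        dropped_collinear=dropped,
    )
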