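"""Two-sample summary-statistics Mendelian randomization.

Implements the summary-level instrumental-variable machinery used to test
whether lifelong exposure to circulating homoarginine (hArg) causally shifts
cardiometabolic traits: per-instrument F-statistics, allele harmonization of
exposure and outcome GWAS rows, per-SNP Wald ratios, inverse-variance-weighted
(IVW) combination via weighted linear regression through the origin with
first-order weights 1/SE_Y^2, a multiplicative random-effects standard error,
and Cochran's Q heterogeneity testing.

The multiplicative random-effects model keeps the fixed-effects point estimate
but inflates its standard error by the residual dispersion
``phi = max(1, sqrt(Q / (J - 1)))`` so that heterogeneous instruments never
yield an over-precise causal estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CausalEstimate",
    "f_statistic",
    "harmonize",
    "wald_ratio",
    "ivw_combine",
    "cochran_q",
    "mr_grid",
    "WEAK_INSTRUMENT_F",
]

#: Conventional weak-instrument threshold for the first-stage F-statistic.
WEAK_INSTRUMENT_F = 10.0

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Columns required in a summary-statistics table (``eaf`` is optional).
SUMMARY_COLUMNS = ["rsid", "effect_allele", "other_allele", "beta", "se", "pvalue", "n"]


@dataclass
class CausalEstimate:
    """Combined IVW causal estimate for one outcome.

    ``theta`` is in outcome units (or log-odds for a binary outcome) per
    1-µmol/L increment in hArg. ``se_re`` is the multiplicative
    random-effects SE used for the confidence interval and p-value;
    ``se_fixed`` is the fixed-effects SE. The point estimate is identical
    under both models by construction.
    """

    theta: float
    se_fixed: float
    se_re: float
    ci_low: float
    ci_high: float
    p_causal: float
    q: float
    df: int
    p_q: float
    n_snps: int
    phi: float
    outcome: str = ""

    @property
    def odds_ratio(self) -> float:
        """exp(theta): OR per 1-µmol/L hArg when the outcome is binary."""
        return math.exp(self.theta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


def f_statistic(beta_x, se_x):
    """First-stage instrument-strength F-statistic, F = (beta/SE)^2.

    Accepts scalars or array-likes. F < 10 conventionally flags a weak
    instrument. Raises ``ValueError`` on non-positive SEs.
    """
    beta_x = np.asarray(beta_x, dtype=float)
    se_x = np.asarray(se_x, dtype=float)
    if np.any(se_x <= 0):
        raise ValueError("SE of the SNP-exposure association must be positive")
    f = (beta_x / se_x) ** 2
    return float(f) if f.ndim == 0 else f


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def _validate_summary(df: pd.DataFrame, what: str) -> pd.DataFrame:
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{what} summary table missing columns: {missing}")
    if df["rsid"].duplicated().any():
        dups = df.loc[df["rsid"].duplicated(), "rsid"].tolist()
        raise ValueError(f"duplicate rsids in {what} summary table: {dups}")
    if (df["se"] <= 0).any():
        raise ValueError(f"non-positive SE in {what} summary table")
    out = df.copy()
    out["effect_allele"] = out["effect_allele"].str.upper()
    out["other_allele"] = out["other_allele"].str.upper()
    return out


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    eaf_ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> pd.DataFrame:
    """Align outcome rows to the exposure's effect alleles.

    For each rsid present in both tables:

    * identical effect/other alleles → kept unchanged;
    * swapped alleles (outcome coded on the other allele) → outcome beta
      negated, ``action='flipped'``;
    * strand-complement matches are recognised the same way;
    * palindromic SNPs (A/T or G/C) are inherently strand-ambiguous: they are
      resolved by effect-allele frequency when both tables report one and
      both frequencies fall outside ``eaf_ambiguity_band``, otherwise dropped
      with reason ``'ambiguous strand'``;
    * anything else is dropped with a stated reason.

    Returns a DataFrame with columns ``rsid, beta_x, se_x, beta_y, se_y,
    weight, ratio, ratio_se, action, reason``; dropped rows carry NaN
    statistics. Raises if no SNP survives.
    """
    exposure = _validate_summary(exposure, "exposure")
    outcome = _validate_summary(outcome, "outcome")

    out_by_rsid = outcome.set_index("rsid")
    rows = []
    for rec in exposure.itertuples(index=False):
        ea_x, oa_x = rec.effect_allele, rec.other_allele
        base = {
            "rsid": rec.rsid,
            "beta_x": rec.beta,
            "se_x": rec.se,
            "beta_y": np.nan,
            "se_y": np.nan,
            "action": "dropped",
            "reason": "",
        }
        if rec.rsid not in out_by_rsid.index:
            base["reason"] = "absent from outcome data"
            rows.append(base)
            continue
        orec = out_by_rsid.loc[rec.rsid]
        ea_y, oa_y = orec["effect_allele"], orec["other_allele"]

        if _is_palindromic(ea_x, oa_x):
            eaf_x = getattr(rec, "eaf", None)
            eaf_y = orec.get("eaf", np.nan)
            if eaf_x is None or pd.isna(eaf_x) or pd.isna(eaf_y):
                base["reason"] = "ambiguous strand"
                rows.append(base)
                continue
            lo, hi = eaf_ambiguity_band
            if lo < eaf_x < hi or lo < eaf_y < hi:
                base["reason"] = "ambiguous strand"
                rows.append(base)
                continue
            same_side = (eaf_x < 0.5) == (eaf_y < 0.5)
            flip = not same_side
        elif (ea_y, oa_y) == (ea_x, oa_x):
            flip = False
        elif (ea_y, oa_y) == (oa_x, ea_x):
            flip = True
        elif (_COMPLEMENT.get(ea_y), _COMPLEMENT.get(oa_y)) == (ea_x, oa_x):
            flip = False
        elif (_COMPLEMENT.get(ea_y), _COMPLEMENT.get(oa_y)) == (oa_x, ea_x):
            flip = True
        else:
            base["reason"] = "allele mismatch"
            rows.append(base)
            continue

        base["beta_y"] = -orec["beta"] if flip else orec["beta"]
        base["se_y"] = orec["se"]
        base["action"] = "flipped" if flip else "kept"
        rows.append(base)

    result = pd.DataFrame(rows)
    retained = result["action"] != "dropped"
    if not retained.any():
        raise ValueError("no usable instruments after harmonization")
    result.loc[retained, "weight"] = 1.0 / result.loc[retained, "se_y"] ** 2
    result.loc[retained, "ratio"] = (
        result.loc[retained, "beta_y"] / result.loc[retained, "beta_x"]
    )
    result.loc[retained, "ratio_se"] = result.loc[retained, "se_y"] / result.loc[
        retained, "beta_x"
    ].abs()
    return result


def wald_ratio(beta_x: float, beta_y: float, se_y: float) -> tuple[float, float]:
    """Per-SNP causal (Wald) ratio with the first-order delta-method SE.

    theta_j = beta_Y / beta_X, SE_j = SE_Y / |beta_X|. The first-order SE
    ignores the sampling error of beta_X — adequate for strong instruments.
    """
    if beta_x == 0:
        raise ValueError("null instrument: beta_x is zero")
    return beta_y / beta_x, se_y / abs(beta_x)


def _retained(harmonized: pd.DataFrame) -> pd.DataFrame:
    return harmonized[harmonized["action"] != "dropped"]


def ivw_combine(harmonized: pd.DataFrame, outcome: str = "") -> CausalEstimate:
    """Inverse-variance-weighted causal estimate with multiplicative random effects.

    Weighted linear regression of the SNP-outcome betas on the SNP-exposure
    betas through the origin with first-order weights ``w_j = 1/SE_Y_j^2``:

        theta_hat = sum(w_j beta_X_j beta_Y_j) / sum(w_j beta_X_j^2)
        SE_fixed  = 1 / sqrt(sum(w_j beta_X_j^2))

    Cochran's Q uses ratio-scale weights ``w'_j = beta_X_j^2 / SE_Y_j^2``; the
    dispersion ``phi = max(1, sqrt(Q/(J-1)))`` multiplies the fixed SE to give
    the random-effects SE so that heterogeneity widens — never narrows — the
    confidence interval. The p-value is two-sided normal on theta/SE_RE.
    """
    kept = _retained(harmonized)
    j = len(kept)
    if j == 0:
        raise ValueError("no retained instruments")
    bx = kept["beta_x"].to_numpy(dtype=float)
    by = kept["beta_y"].to_numpy(dtype=float)
    sey = kept["se_y"].to_numpy(dtype=float)
    if np.any(sey <= 0):
        raise ValueError("non-positive outcome SE")

    w = 1.0 / sey**2
    denom = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / denom
    se_fixed = 1.0 / math.sqrt(denom)

    ratios = by / bx
    q = float(np.sum((bx**2 / sey**2) * (ratios - theta) ** 2))
    df = j - 1
    phi = max(1.0, math.sqrt(q / df)) if df >= 1 else 1.0
    se_re = phi * se_fixed
    z = theta / se_re
    p_causal = 2.0 * stats.norm.sf(abs(z))
    p_q = float(stats.chi2.sf(q, df)) if df >= 1 else float("nan")
    half = stats.norm.ppf(0.975) * se_re
    return CausalEstimate(
        theta=theta,
        se_fixed=se_fixed,
        se_re=se_re,
        ci_low=theta - half,
        ci_high=theta + half,
        p_causal=float(p_causal),
        q=q,
        df=df,
        p_q=p_q,
        n_snps=j,
        phi=phi,
        outcome=outcome,
    )


def cochran_q(harmonized: pd.DataFrame, theta: float) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic across the per-SNP causal ratios.

    Q = sum_j w'_j (theta_j - theta)^2 with w'_j = beta_X_j^2 / SE_Y_j^2;
    under homogeneity Q ~ chi^2 with J-1 degrees of freedom. Requires J >= 2.
    """
    kept = _retained(harmonized)
    j = len(kept)
    if j < 2:
        raise ValueError("heterogeneity undefined with fewer than 2 instruments")
    bx = kept["beta_x"].to_numpy(dtype=float)
    by = kept["beta_y"].to_numpy(dtype=float)
    sey = kept["se_y"].to_numpy(dtype=float)
    q = float(np.sum((bx**2 / sey**2) * (by / bx - theta) ** 2))
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


def mr_grid(
    exposure: pd.DataFrame,
    outcomes: dict[str, pd.DataFrame],
    exposure_scale_factor: float = 1.0,
) -> pd.DataFrame:
    """Run harmonize → IVW for every outcome; per-outcome failures never abort.

    ``exposure_scale_factor`` rescales the exposure betas (and SEs) before
    combination — use the exposure SD (0.65 µmol/L for hArg) when the
    exposure GWAS reports per-SD betas, so estimates stay per 1-µmol/L.

    Returns a long-format table with one row per outcome: n_snps, theta,
    se_re, 95% CI, p_causal, Q, df, p_Q; failed cells carry NaN plus the
    error message.
    """
    exp = exposure.copy()
    if exposure_scale_factor != 1.0:
        exp["beta"] = exp["beta"] * exposure_scale_factor
        exp["se"] = exp["se"] * exposure_scale_factor

    rows = []
    for name, out_df in outcomes.items():
        try:
            est = ivw_combine(harmonize(exp, out_df), outcome=name)
            rows.append(
                {
                    "outcome": name,
                    "n_snps": est.n_snps,
                    "theta": est.theta,
                    "se": est.se_re,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p_causal": est.p_causal,
                    "q": est.q,
                    "df_q": est.df,
                    "p_q": est.p_q,
                    "error": "",
                }
            )
        except (ValueError, KeyError) as exc:
            rows.append(
                {
                    "outcome": name,
                    "n_snps": 0,
                    "theta": np.nan,
                    "se": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_causal": np.nan,
                    "q": np.nan,
                    "df_q": 0,
                    "p_q": np.nan,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)
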