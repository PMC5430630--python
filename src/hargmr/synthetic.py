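"""Synthetic cohort and two-sample GWAS summary-statistic generators.

Emulates the statistical structure of a young-adult population cohort
(n ≈ 2,100, 54.6% women, aged 24–39) with serum homoarginine (hArg),
standard cardiometabolic risk factors, an NMR-style metabolite panel, three
hArg-associated instrument SNPs (GATM rs1153858, CPS1 rs1047891,
AGXT2 rs37369), and 6/7/10-year follow-up measurements — plus matched
two-sample GWAS summary statistics under a configurable causal effect,
per-SNP pleiotropy and heterogeneity. Everything downstream of data
collection is therefore testable without any external download.

ln-hArg is built additively on the log scale: intercept + per-allele SNP
effects × dosage + Gaussian noise, with the lead-SNP effect solved
analytically so its expected variance share equals ``variance_explained_lead``
(default 5.3%). Trait marginals target the requested means/SDs; strictly
positive skewed traits (triglycerides, CRP, insulin, SHBG) are drawn
lognormal with moment-matched parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortParams",
    "OutcomeModel",
    "SummarySimParams",
    "generate_cohort",
    "generate_two_sample_summary",
    "SNP_IDS",
    "LEAD_SNP",
    "TABLE1_MEANS_SDS",
]

SNP_IDS = ("rs1153858", "rs1047891", "rs37369")
LEAD_SNP = "rs1153858"

#: Baseline trait marginals (mean, SD) in clinical units for the default
#: cohort: hArg µmol/L, lipids and glucose mmol/L, BP mmHg, BMI kg/m²,
#: waist cm, insulin IU/L, CRP mg/L, SHBG nmol/L, age years.
TABLE1_MEANS_SDS: dict[str, tuple[float, float]] = {
    "age": (31.7, 5.0),
    "harg": (1.85, 0.65),
    "ln_harg": (0.56, 0.34),
    "ldl": (3.27, 0.84),
    "hdl": (1.29, 0.31),
    "tg": (1.26, 0.64),
    "sbp": (117.0, 13.0),
    "dbp": (72.0, 11.0),
    "crp": (1.9, 4.0),
    "glucose": (5.1, 0.85),
    "insulin": (7.7, 5.7),
    "bmi": (25.0, 4.4),
    "waist": (84.0, 12.0),
}

#: SHBG (nmol/L) is not part of the published baseline table; these are
#: field-typical young-adult values, higher and more dispersed in women.
SHBG_MEANS_SDS = {"male": (35.0, 15.0), "female": (55.0, 30.0)}

_LOGNORMAL_TRAITS = ("tg", "crp", "insulin", "shbg")
_FOLLOWUP_TRAITS = ("waist", "tg", "hdl", "sbp", "dbp", "glucose", "insulin", "bmi")


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic generating model for one incident binary outcome.

    log-odds = intercept + log_or_harg · z(ln hArg) + Σ covariate log-ORs on
    z-scored covariates. Horizon in years selects the follow-up wave.
    """

    intercept: float
    log_or_harg: float
    covariate_log_ors: dict[str, float] = field(default_factory=dict)
    horizon: int = 10


def _default_outcomes() -> dict[str, OutcomeModel]:
    # Intercepts give realistic 10-year incidences in young adults
    # (hyperglycaemia ~15%, abdominal obesity ~10%, T2DM ~2%); hArg log-ORs
    # echo the observational effect sizes seen in this age group.
    return {
        "hyperglycaemia": OutcomeModel(-1.75, math.log(1.3), {"bmi": 0.25}),
        "abdominal_obesity": OutcomeModel(-2.2, math.log(1.6), {"bmi": 0.8}),
        "t2dm": OutcomeModel(-4.0, math.log(1.55), {"glucose": 0.5}),
    }


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic cohort generator (defaults: the stated
    young-adult cohort marginals)."""

    n_participants: int = 2106
    female_fraction: float = 0.546
    baseline_means_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE1_MEANS_SDS)
    )
    smoking_prevalence: float = 0.247
    family_history_prevalence: float = 0.133
    oc_use_prevalence: float = 0.25
    bp_treatment_prevalence: float = 0.03
    snp_ids: tuple[str, ...] = SNP_IDS
    snp_effect_alleles: tuple[str, ...] = ("T", "A", "C")
    snp_other_alleles: tuple[str, ...] = ("C", "C", "T")
    snp_eafs: tuple[float, ...] = (0.3, 0.3, 0.3)
    #: ln-hArg variance share of the lead SNP; if None, a per-allele effect
    #: of ~0.25 µmol/L at the mean is used instead.
    variance_explained_lead: float | None = 0.053
    per_allele_effect_lead: float = 0.25
    #: non-lead per-allele ln-scale effects relative to the lead effect
    snp_relative_effects: tuple[float, ...] = (1.0, 0.7, -0.5)
    outcome_log_odds: dict[str, OutcomeModel] = field(default_factory=_default_outcomes)
    n_metabolite_blocks: int = 25
    metabolites_per_block: int = 4
    metabolite_block_rho: float = 0.96
    #: per-block association betas (SD metabolite per SD ln-hArg); cycled
    metabolite_block_betas: tuple[float, ...] = (0.3, 0.0, -0.3, 0.0, 0.0)
    followup_attendance: float = 0.85
    followup_carryover: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")
        for name, p in [
            ("female_fraction", self.female_fraction),
            ("smoking_prevalence", self.smoking_prevalence),
            ("followup_attendance", self.followup_attendance),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for eaf in self.snp_eafs:
            if not 0.0 < eaf < 1.0:
                raise ValueError(f"snp_eafs must be strictly inside (0,1), got {eaf}")
        for trait, (_, sd) in self.baseline_means_sds.items():
            if sd <= 0:
                raise ValueError(f"SD for {trait} must be positive")
        if self.variance_explained_lead is not None and not (
            0.0 <= self.variance_explained_lead < 1.0
        ):
            raise ValueError("variance_explained_lead must be in [0, 1)")
        if not 0.0 <= self.metabolite_block_rho < 1.0:
            raise ValueError("metabolite_block_rho must be in [0, 1)")


def _lead_ln_effect(params: CohortParams) -> float:
    mean_h, _ = params.baseline_means_sds["harg"]
    _, sd_ln = params.baseline_means_sds["ln_harg"]
    p = params.snp_eafs[0]
    if params.variance_explained_lead is not None:
        return math.sqrt(
            params.variance_explained_lead * sd_ln**2 / (2.0 * p * (1.0 - p))
        )
    # ~0.25 µmol/L per allele at the cohort mean, expressed on the log scale
    return math.log1p(params.per_allele_effect_lead / mean_h)


def snp_ln_effects(params: CohortParams) -> np.ndarray:
    """Per-allele effects of the three SNPs on ln-hArg (log-µmol/L units)."""
    lead = _lead_ln_effect(params)
    return lead * np.asarray(params.snp_relative_effects, dtype=float)


def _lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort table; a pure function of (params, seed).

    Columns: id, sex, age, baseline traits, smoker/family_history/oc_use/
    bp_treatment flags, dosage_<rsid> genotype dosages, harg & ln_harg,
    metabolite columns ``met_###``, attendance flags ``attended_{6,7,10}y``,
    follow-up traits ``<trait>_10y`` plus ``agatston_7y``, ``hba1c_10y``,
    ``imt``/``imt_6y``, ``distensibility``/``distensibility_6y``, and
    incident-outcome flags ``inc_<name>`` drawn from the configured logistic
    models (NA for non-attenders of that horizon).
    """
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    means = params.baseline_means_sds

    df = pd.DataFrame({"id": [f"P{i:06d}" for i in range(n)]})
    df["sex"] = np.where(
        rng.random(n) < params.female_fraction, "female", "male"
    )
    female = df["sex"].to_numpy() == "female"
    df["age"] = rng.normal(*means["age"], size=n)

    # genotypes under Hardy-Weinberg
    effects = snp_ln_effects(params)
    dosages = np.empty((n, len(params.snp_ids)), dtype=int)
    for j, (rsid, eaf) in enumerate(zip(params.snp_ids, params.snp_eafs)):
        dosages[:, j] = rng.binomial(2, eaf, size=n)
        df[f"dosage_{rsid}"] = dosages[:, j]

    # ln-hArg: genetic signal + residual noise, total variance matching the
    # requested ln-scale SD; small male-female mean shift as observed.
    mean_ln, sd_ln = means["ln_harg"]
    genetic = dosages @ effects
    var_gen = float(
        np.sum(
            effects**2
            * 2.0
            * np.asarray(params.snp_eafs)
            * (1.0 - np.asarray(params.snp_eafs))
        )
    )
    if var_gen >= sd_ln**2:
        raise ValueError("genetic variance exceeds total ln-hArg variance")
    sex_shift = 0.045  # ± around the overall mean (men 0.61 vs women 0.52)
    resid_sd = math.sqrt(sd_ln**2 - var_gen - sex_shift**2)
    intercept = mean_ln - genetic.mean() + 0.0
    ln_harg = (
        intercept
        + genetic
        + np.where(female, -sex_shift, sex_shift)
        + rng.normal(0.0, resid_sd, size=n)
    )
    df["ln_harg"] = ln_harg
    df["harg"] = np.exp(ln_harg)
    z_ln_harg = (ln_harg - ln_harg.mean()) / ln_harg.std(ddof=1)

    for trait in ("ldl", "hdl", "sbp", "dbp", "glucose", "bmi", "waist"):
        df[trait] = rng.normal(*means[trait], size=n)
    for trait in _LOGNORMAL_TRAITS:
        if trait == "shbg":
            continue
        mu, sigma = _lognormal_moments(*means[trait])
        df[trait] = rng.lognormal(mu, sigma, size=n)
    mu_f, sig_f = _lognormal_moments(*SHBG_MEANS_SDS["female"])
    mu_m, sig_m = _lognormal_moments(*SHBG_MEANS_SDS["male"])
    df["shbg"] = np.where(
        female, rng.lognormal(mu_f, sig_f, n), rng.lognormal(mu_m, sig_m, n)
    )
    df.loc[df["glucose"] < 3.0, "glucose"] = 3.0
    df.loc[df["hdl"] < 0.4, "hdl"] = 0.4

    df["smoker"] = rng.random(n) < params.smoking_prevalence
    df["family_history"] = rng.random(n) < params.family_history_prevalence
    df["oc_use"] = np.where(female, rng.random(n) < params.oc_use_prevalence, False)
    df["bp_treatment"] = rng.random(n) < params.bp_treatment_prevalence
    df["type1_diabetes"] = False
    df["glucose_med"] = rng.random(n) < 0.004
    df["t2dm_dx"] = df["glucose_med"] & (rng.random(n) < 0.8)

    # carotid phenotypes: mild age dependence, sex offset
    age_c = df["age"] - df["age"].mean()
    df["imt"] = 0.58 + 0.004 * age_c + np.where(female, -0.01, 0.01) + rng.normal(
        0, 0.08, n
    )
    df["distensibility"] = (
        2.2 - 0.03 * age_c - np.where(female, -0.05, 0.05) + rng.normal(0, 0.45, n)
    )

    # metabolite panel: equicorrelated blocks sharing a latent factor, with a
    # per-block ln-hArg signal; concentrations are lognormal (non-negative).
    rho = params.metabolite_block_rho
    betas = params.metabolite_block_betas
    met_cols = {}
    k = 0
    for b in range(params.n_metabolite_blocks):
        beta = betas[b % len(betas)]
        factor = rng.normal(0.0, 1.0, size=n)
        for _ in range(params.metabolites_per_block):
            noise = rng.normal(0.0, 1.0, size=n)
            latent = beta * z_ln_harg + math.sqrt(
                max(0.0, 1.0 - beta**2)
            ) * (math.sqrt(rho) * factor + math.sqrt(1.0 - rho) * noise)
            met_cols[f"met_{k:03d}"] = np.exp(0.4 * latent)
            k += 1
    df = pd.concat([df, pd.DataFrame(met_cols, index=df.index)], axis=1)

    # follow-up attendance & traits (AR(1) carry-over around the baseline mean)
    for horizon in (6, 7, 10):
        df[f"attended_{horizon}y"] = rng.random(n) < params.followup_attendance
    phi = params.followup_carryover
    for trait in _FOLLOWUP_TRAITS:
        mean_t, sd_t = means[trait]
        fup = mean_t + phi * (df[trait] - mean_t) + math.sqrt(
            1.0 - phi**2
        ) * sd_t * rng.normal(0, 1, n)
        fup = np.maximum(fup, 0.1)
        df[f"{trait}_10y"] = np.where(df["attended_10y"], fup, np.nan)
    df["hba1c_10y"] = np.where(
        df["attended_10y"], rng.normal(5.4, 0.4, n).clip(3.5), np.nan
    )
    cac = (rng.random(n) < 0.19) * rng.lognormal(2.0, 1.2, n)
    df["agatston_7y"] = np.where(df["attended_7y"], np.round(cac, 1), np.nan)
    for var, drift, noise_sd in (("imt", 0.04, 0.05), ("distensibility", -0.15, 0.3)):
        fup = df[var] + drift + rng.normal(0, noise_sd, n)
        df[f"{var}_6y"] = np.where(df["attended_6y"], fup, np.nan)

    # incident binary outcomes from the stated logistic models
    for name, model in params.outcome_log_odds.items():
        lin = model.intercept + model.log_or_harg * z_ln_harg
        for cov, lor in model.covariate_log_ors.items():
            x = df[cov].to_numpy(dtype=float)
            lin = lin + lor * (x - x.mean()) / x.std(ddof=1)
        p = 1.0 / (1.0 + np.exp(-lin))
        drawn = rng.random(n) < p
        attended = df[f"attended_{model.horizon}y"].to_numpy()
        col = pd.array(drawn, dtype="boolean")
        col[~attended] = pd.NA
        df[f"inc_{name}"] = col

    return df


@dataclass(frozen=True)
class SummarySimParams:
    """Parameters of the two-sample summary-statistics generator.

    ``true_effect`` is the causal effect θ in outcome units per µmol/L hArg;
    ``pleiotropy_alphas`` are direct SNP→outcome effects (exclusion-
    restriction violations); ``heterogeneity_sd`` adds balanced per-SNP
    effect noise. Exposure and outcome draws are independent (no sample
    overlap).
    """

    n_snps: int = 3
    true_effect: float = 0.0
    exposure_betas: tuple[float, ...] = (0.25, 0.20, -0.16)
    exposure_sd: float = 0.65
    outcome_sd: float = 1.0
    exposure_n: int = 5143
    outcome_n: int = 100_000
    eafs: tuple[float, ...] = (0.3, 0.3, 0.3)
    pleiotropy_alphas: tuple[float, ...] | None = None
    heterogeneity_sd: float = 0.0
    seed: int = 0
    snp_ids: tuple[str, ...] = SNP_IDS
    effect_alleles: tuple[str, ...] = ("T", "A", "C")
    other_alleles: tuple[str, ...] = ("C", "C", "T")

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("need at least one SNP")
        if len(self.exposure_betas) < self.n_snps:
            raise ValueError("exposure_betas shorter than n_snps")
        if self.exposure_n < 2 or self.outcome_n < 2:
            raise ValueError("sample sizes must exceed 1")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be non-negative")


def generate_two_sample_summary(
    params: SummarySimParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw exposure and outcome GWAS summary tables for the instruments.

    β̂X_j ~ N(βX_j, seX_j²) and β̂Y_j ~ N(θ·βX_j + α_j + η_j, seY_j²) with
    η_j ~ N(0, heterogeneity_sd²) and SEs from the per-allele regression
    approximation se = sd_trait / sqrt(2·p·(1−p)·n), so SEs scale as 1/√n.
    """
    params = params or SummarySimParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    j = params.n_snps

    bx = np.asarray(params.exposure_betas[:j], dtype=float)
    eafs = np.asarray((params.eafs * j)[:j], dtype=float)
    alphas = np.zeros(j)
    if params.pleiotropy_alphas is not None:
        alphas = np.asarray((tuple(params.pleiotropy_alphas) + (0.0,) * j)[:j])

    het = rng.normal(0.0, params.heterogeneity_sd, size=j) if params.heterogeneity_sd else np.zeros(j)
    se_x = params.exposure_sd / np.sqrt(2.0 * eafs * (1.0 - eafs) * params.exposure_n)
    se_y = params.outcome_sd / np.sqrt(2.0 * eafs * (1.0 - eafs) * params.outcome_n)

    bhat_x = rng.normal(bx, se_x)
    bhat_y = rng.normal(params.true_effect * bx + alphas + het, se_y)

    from scipy import stats as _st

    def table(beta, se, n_samples):
        ids = list(params.snp_ids[:j]) + [
            f"rs_extra{i}" for i in range(max(0, j - len(params.snp_ids)))
        ]
        return pd.DataFrame(
            {
                "rsid": ids[:j],
                "effect_allele": (params.effect_alleles * j)[:j],
                "other_allele": (params.other_alleles * j)[:j],
                "beta": beta,
                "se": se,
                "pvalue": 2.0 * _st.norm.sf(np.abs(beta / se)),
                "n": n_samples,
                "eaf": eafs,
            }
        )

    return table(bhat_x, se_x, params.exposure_n), table(bhat_y, se_y, params.outcome_n)
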