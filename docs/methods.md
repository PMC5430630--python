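# Methods

This note documents the statistical models implemented in `hargmr`, the
assumptions behind them, the synthetic world the generators state, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Two-sample Mendelian randomization (`hargmr.mr`)

**Model.** Each instrument SNP *j* carries a per-allele effect βₓⱼ on serum
hArg (µmol/L) and, under the exclusion restriction, affects an outcome only
through hArg, so the SNP–outcome effect is θ·βₓⱼ for causal effect θ. With
summary estimates β̂ₓⱼ (SE σₓⱼ) and β̂ᵧⱼ (SE σᵧⱼ) from non-overlapping
samples, the combined estimate is weighted linear regression of β̂ᵧ on β̂ₓ
through the origin with first-order weights 1/σᵧⱼ² — algebraically the
inverse-variance-weighted mean of the per-SNP Wald ratios β̂ᵧⱼ/β̂ₓⱼ with
ratio SEs σᵧⱼ/|β̂ₓⱼ|. The identity between the two formulations is asserted
in tests; the regression form is the canonical implementation path.

**First-order SEs.** The Wald-ratio SE ignores the sampling error of β̂ₓ.
This is adequate when instruments are strong (here F = (β̂ₓ/σₓ)² is in the
hundreds) but induces a small attenuation of order 1/F in θ̂, visible in
the recovery simulations as a bias well inside 3 Monte-Carlo SEs.
Second-order corrections are a possible extension, not implemented.

**Multiplicative random effects.** φ = max(1, √(Q/(J−1))) multiplies the
fixed-effects SE. The floor at 1 means under-dispersion never produces an
interval narrower than fixed effects — the model exists to avoid
over-precise estimates under heterogeneity, not to reward homogeneity. A
consequence, confirmed by the calibration suite, is that the causal test is
slightly conservative under the null (empirical type-I error ≈ 0.036–0.04
at nominal 0.05 with J = 3), since φ absorbs upward Q fluctuations.
p-values use the normal distribution (summary-level asymptotics), not t.

**Harmonization.** Outcome rows are aligned to the exposure's effect
alleles: exact and swapped matches (and their strand complements) are kept
or sign-flipped; palindromic SNPs (A/T, G/C) are resolved by effect-allele
frequency only when both sides report one and both are outside
(0.42, 0.58), otherwise dropped with reason "ambiguous strand" — guessing
strand is never attempted. Dropped rows stay in the output with their
reason, so instrument loss is auditable.

**Exposure units.** Estimates are per 1-µmol/L hArg. If an exposure GWAS
reports per-SD betas, `mr_grid(..., exposure_scale_factor=0.65)` (the
cohort SD of hArg) converts before combination; the p-values are invariant
to this rescaling, only the effect scale changes.

## 2. Phenotyping (`hargmr.phenotyping`)

Outcome flags follow the harmonized metabolic-syndrome criteria plus
obesity, high insulin, T2DM, coronary calcification and high-risk carotid
phenotypes; the boundary conventions are exactly the quoted ones
(waist ≥ 102/88 cm, triglycerides > 1.7 mmol/L strictly, HDL < 1.0/1.3
strictly, BP ≥ 130 or ≥ 85 mmHg or treated, glucose ≥ 5.6, BMI ≥ 30,
Agatston ≥ 1, T2DM at glucose ≥ 7.0 or HbA1c ≥ 6.5 % or glucose-lowering
medication without type 1 diabetes or physician diagnosis).

Multi-criterion flags combine with three-valued (Kleene) OR: an observed
True criterion decides the flag even when other inputs are missing (so BP
treatment alone suffices with unmeasured BP), while a flag is never False
merely because an input was unobserved — missing stays missing. A criterion
whose input column is absent from the table entirely is skipped rather than
treated as missing, so baseline tables without HbA1c still classify T2DM
from glucose and medication.

Percentile-based flags (high insulin; high-risk IMT; low distensibility)
carry their cut, stratum and comparison operator in a `PercentileReference`.
Quantiles use linear interpolation (Hyndman–Fan type 7, numpy's default);
the rule label is stored so alternatives remain switchable. The
within-top-decile insulin rule compares strictly (">"), while the fixed
operational cuts 18.8/15.2 IU/L are quoted inclusively ("≥") and are
provided as constants with that comparison. IMT/distensibility strata are
3-year age bands × sex by default (band width configurable; out-of-range
ages clamp to the nearest band).

Incidence bookkeeping: at-risk = baseline flag observed False and follow-up
flag observed; incident = at-risk and follow-up True. Prevalent cases and
unobservable follow-ups contribute nothing.

## 3. Cross-sectional analyses (`hargmr.crosssectional`)

**Preparation.** Zeros in each metabolite column become half the column's
minimum positive value (a detection-limit estimate), then natural log, then
centring/scaling to unit SD within the scaling stratum (pooled or per-sex).
An all-zero column is an error naming the column, as is a constant column.
hArg itself is ln-transformed and SD-scaled within the same stratum scheme
as the metabolites (configurable; per-stratum by default), so scan betas
are SD-per-SD.

**Effective number of tests.** k is the smallest number of principal
components of the column correlation matrix whose cumulative explained
variance reaches the target (default 0.95); the per-test threshold is
alpha/k. For a matrix of B equal blocks of perfectly duplicated columns the
spectrum has exactly B nonzero eigenvalues of equal share, so
k = ceil(target·B) analytically — 24 for B = 25 at 0.95, giving
0.05/24 ≈ 0.002 at the precision that divisor is conventionally quoted.
On realistic correlated-but-not-degenerate data (e.g. the synthetic panel's
25 blocks at within-block correlation 0.96) the procedure returns k = 25.
Sample eigenvalue spread matters at small n; tests that need the analytic
spectrum use exactly orthogonalized block bases.

**Scan and interactions.** Per metabolite and stratum, OLS of the prepared
metabolite on SD-scaled ln-hArg plus covariates; p-values from the t
distribution on the residual degrees of freedom (stratum sizes near 1,000
make this nearly normal, but the t form is kept). Rank-deficient designs
raise, listing the candidate covariates. Sex differences use
Z = (β_m − β_f)/√(SE_m² + SE_f²) against the standard normal; the BMI
interaction adds the product of SD-scaled ln-hArg and BMI to the model, and
its coefficient is invariant to centring BMI.

**Stepwise AIC.** Bidirectional greedy search starting from the full model
(matching the default of the commonly used stepwise procedure;
`start="intercept"` is available). Each round scores all single additions
and deletions and applies the lowest-AIC move; ties break toward the
smaller model; the search stops at a local optimum (verified in tests by
exhaustive neighbour enumeration). Gaussian AIC from the OLS likelihood is
used throughout; only AIC differences matter, so the additive constant is
irrelevant. Perfectly collinear candidates are dropped with a warning
before the search (greedy screen in column order, keeping the earlier
column of a collinear pair).

## 4. Incident-outcome models (`hargmr.longitudinal`)

Logistic regression of each incident outcome on SD-scaled ln-hArg within
sex strata. Tier 1 is unadjusted; tier 2 adds the baseline cardiometabolic
risk factors (age, LDL, HDL, ln TG, systolic and diastolic BP, ln CRP,
glucose, ln insulin, BMI, waist, daily smoking, family history of CAD) —
BMI and waist are both retained despite collinearity-proneness, with a
warning on rank deficiency; tier 3 adds ln SHBG and, in women,
oral-contraceptive use. Skewed covariates enter log-transformed. ORs are
per 1-SD ln-hArg with Wald CIs; zero events raise, all-events raise, and
suspected separation (non-convergence or SE > 50) is flagged on the
result. The grid runner never aborts: failed cells carry NaN and the error
message.

## 5. Synthetic world (`hargmr.synthetic`)

The cohort generator states a young-adult population: n = 2,106, 54.6 %
women, age 31.7 (5.0) years, hArg 1.85 (0.65) µmol/L with
ln-hArg 0.56 (0.34), and the usual risk-factor marginals (LDL 3.27 (0.84),
HDL 1.29 (0.31), TG 1.26 (0.64) mmol/L; BP 117 (13)/72 (11) mmHg;
glucose 5.1 (0.85) mmol/L; insulin 7.7 (5.7) IU/L; BMI 25.0 (4.4) kg/m²;
waist 84 (12) cm; CRP 1.9 (4.0) mg/L; 24.7 % daily smokers; 13.3 % family
history). Strictly positive skewed traits (TG, CRP, insulin, SHBG) are
lognormal with moment-matched parameters. SHBG is not part of the stated
baseline table; field-typical young-adult values are used (women
55 (30) nmol/L, men 35 (15)).

ln-hArg is additive on the log scale: intercept + Σ per-allele effects ×
dosage + sex shift ± 0.045 + Gaussian noise, with total variance pinned to
0.34². Genotypes are Hardy–Weinberg draws at configurable effect-allele
frequencies (default 0.3 — the frequencies are not stated in the source
material). The lead-SNP effect is solved analytically so its expected
ln-hArg variance share equals 5.3 % (the stated instrument strength); when
that share is unset, the per-allele effect defaults to ~0.25 µmol/L at the
mean, i.e. ln(1 + 0.25/1.85) on the log scale. Non-lead effects default to
0.7 and −0.5 of the lead effect. No linkage disequilibrium between the
three SNPs is modelled (they are treated as independent).

Metabolites form 25 equicorrelated blocks (within-block ρ = 0.96, block
size 4 by default — 100 columns rather than the platform's 228, for test
speed; configurable) sharing a latent factor plus a per-block ln-hArg
signal, exponentiated to non-negative concentrations. With these defaults
the effective-tests procedure on a generated panel returns k = 25,
reproducing the 0.05/25 divisor used as the scan threshold.

Incident outcomes are Bernoulli draws from stated logistic models
(log-odds = intercept + log-OR·z(ln-hArg) + covariate terms); defaults give
10-year incidences of ~15 % (hyperglycaemia), ~10 % (abdominal obesity) and
~2 % (T2DM) with hArg log-ORs echoing the observational effect sizes in
this age group (1.3, 1.6, 1.55). Follow-up attendance is independent
Bernoulli (0.85) per horizon; follow-up traits follow an AR(1) carry-over
(ρ = 0.7) around the baseline mean. These flags are NA for non-attenders,
exercising the prevalent/incident bookkeeping.

The two-sample generator draws β̂ₓⱼ ~ N(βₓⱼ, σₓⱼ²) and
β̂ᵧⱼ ~ N(θβₓⱼ + αⱼ + ηⱼ, σᵧⱼ²) with SEs from the per-allele regression
approximation σ = sd_trait/√(2p(1−p)n), independent samples (no overlap),
configurable pleiotropy αⱼ and balanced heterogeneity ηⱼ. Defaults
(βₓ = 0.25, 0.20, −0.16 µmol/L at n = 5,143, EAF 0.3) put the instrument
F-statistics inside the stated 120–370 band.

**What a green test does not establish.** The generators emulate marginal
distributions, one genetic signal and block correlation — not real LD
structure, assay noise, population stratification, time-varying
confounding, or the actual joint distribution of risk factors (baseline
traits are mutually independent apart from the stated links). Green
calibration/recovery tests establish internal statistical correctness of
the estimators under the stated model, not reproduction of any real
cohort's estimates, which depend on individual-level data not available
here.

## 6. Numerical conventions

* Quantiles: Hyndman–Fan type 7 everywhere.
* Eigendecomposition: `numpy.linalg.eigvalsh` on the correlation matrix,
  eigenvalues clipped at 0, cumulative share compared with a 1e-12 slack.
* AIC comparisons use a 1e-10 tie tolerance, ties resolved toward fewer
  terms.
* Seeds: every generator is a pure function of (params, seed) via
  `numpy.random.default_rng`; the CLI derives stage seeds as seed, seed+1.
* Missing data: no imputation anywhere; analyses are complete-case within
  their own variable sets; the NA token in all TSV dialects is "NA".

## Known limitations

* First-order Wald SEs only (no second-order correction, no MR-Egger or
  median/mode estimators, no LD-aware multi-SNP models).
* The phenotyping engine ingests tabular trait values only (no ICD codes).
* No survival modelling: incidence is binary per horizon, as specified.
* The stepwise search is greedy; it guarantees a local AIC optimum, not the
  global one.
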