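# hargmr

Observational and two-sample Mendelian-randomization (MR) analysis of serum
L-homoarginine (hArg) and cardiometabolic outcomes, packaged as a tested,
reusable pipeline that runs end-to-end on synthetic data.

hArg is a non-proteinogenic amino acid whose circulating level is positively
associated with several cardiometabolic risk factors in observational
cohorts. The package separates the two questions such data can address:

* **Is hArg a biomarker?** Rule-based incident-outcome phenotyping
  (harmonized metabolic-syndrome components, obesity, high insulin, type 2
  diabetes, coronary calcification, high-risk carotid phenotypes) feeds
  sex-stratified logistic models of 6/7/10-year incident outcomes on
  SD-scaled ln-hArg, in three nested adjustment tiers, plus a sex-stratified
  metabolome-wide linear-regression scan with an effective-number-of-tests
  multiple-testing threshold and a bidirectional stepwise-AIC model of the
  clinical determinants of hArg.
* **Is hArg causal?** A two-sample summary-statistics MR engine using three
  hArg-associated variants (*GATM* rs1153858, *CPS1* rs1047891, *AGXT2*
  rs37369) as instruments.

## The MR model

For instrument *j* with SNP–exposure association β̂ₓⱼ (µmol/L hArg per
effect allele) and SNP–outcome association β̂ᵧⱼ (SE σᵧⱼ), the combined
causal effect is the weighted regression of β̂ᵧ on β̂ₓ through the origin
with first-order weights wⱼ = 1/σᵧⱼ²:

    θ̂  = Σ wⱼ β̂ₓⱼ β̂ᵧⱼ / Σ wⱼ β̂ₓⱼ²          SE_fixed = (Σ wⱼ β̂ₓⱼ²)^(-1/2)

Heterogeneity between the per-SNP Wald ratios θ̂ⱼ = β̂ᵧⱼ/β̂ₓⱼ is measured by
Cochran's Q = Σ (β̂ₓⱼ²/σᵧⱼ²)(θ̂ⱼ − θ̂)², referred to χ²(J−1). The
multiplicative random-effects model keeps the fixed-effects point estimate
and inflates its SE by φ = max(1, √(Q/(J−1))), so pleiotropy-driven
heterogeneity can widen but never narrow the confidence interval.
Instrument strength is the first-stage F = (β̂ₓ/σₓ)², with F < 10 flagged
as weak. Allele harmonization (including palindromic-SNP resolution by
allele frequency) aligns outcome rows to the exposure's effect alleles
before combination.

## Worked example

```python
from hargmr import (SummarySimParams, generate_two_sample_summary,
                    harmonize, ivw_combine, f_statistic)

exp, out = generate_two_sample_summary(SummarySimParams(seed=7, true_effect=0.0))
est = ivw_combine(harmonize(exp, out), outcome="fasting_glucose")
print(f"theta = {est.theta:.4f}  SE(RE) = {est.se_re:.4f} "
      f"95% CI [{est.ci_low:.4f}, {est.ci_high:.4f}]")
print(f"p_causal = {est.p_causal:.3f}   Q = {est.q:.3f} "
      f"(df={est.df}, p_Q = {est.p_q:.3f})")
```

prints

```
theta = -0.0057  SE(RE) = 0.0135 95% CI [-0.0321, 0.0207]
p_causal = 0.672   Q = 1.805 (df=2, p_Q = 0.406)
```

i.e. with a null generating effect the combined causal estimate per
1-µmol/L hArg is near zero, its confidence interval covers zero
(p = 0.67), and Cochran's Q finds no more heterogeneity between the three
per-variant estimates than chance would produce (p = 0.41). The instrument
F-statistics for this draw are 320, 213 and 137 — all well above the
weak-instrument threshold of 10.

The full synthetic pipeline is one command:

```sh
hargmr all --seed 5 --out runs/demo
```

which writes the cohort, summary statistics, baseline/follow-up outcome
flags, scan results with the effective-tests threshold, the incident-model
grid and the MR table, plus a JSON run manifest; identical seeds give
byte-identical outputs. Individual stages are available as `hargmr
simulate|phenotype|scan|incident|mr`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from scratch, (t1) the per-test significance threshold produced
by the effective-number-of-tests procedure on a standardized matrix of 25
mutually independent blocks of duplicated columns (alpha 0.05, 95%
cumulative-variance criterion), and (t2) the relative per-allele increase
in serum hArg (percent of the cohort mean) for the lead variant, measured
by regression on genotype dosage in a large synthetic cohort.
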