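# mrcost

Mendelian-randomization (MR) analysis of the causal effect of adiposity on
inpatient hospital costs, with a synthetic biobank-cohort simulator that
makes every stage of the analysis testable without restricted-access data.

## The problem

Observational estimates of the association between body mass index
(BMI, kg/m²) and healthcare costs are contaminated by measurement error,
reverse causation (illness changes weight) and omitted common causes.
MR treats germline genetic variants as instrumental variables: alleles are
allocated essentially at random at conception, so SNPs that raise BMI can
identify the causal effect of BMI on costs — provided the instruments are
valid. This package implements the full estimator and diagnostics suite
such a study needs, for biostatisticians and health economists:

* **Summary-data estimators** (`mrcost.estimators`): per-SNP Wald ratios
  Γ̂ⱼ/γ̂ⱼ; the inverse-variance-weighted (IVW) estimator
  β̂ = Σγ̂ⱼ²σ_Yⱼ⁻²·(Γ̂ⱼ/γ̂ⱼ) / Σγ̂ⱼ²σ_Yⱼ⁻² with fixed or multiplicative
  random effects; Cochran's Q (χ²_{J−1}); MR-Egger regression (slope +
  pleiotropy intercept under InSIDE); the penalized weighted median;
  the weighted mode; the robust adjusted profile score (RAPS); and
  multivariable MR for two exposures.
* **Individual-level analyses** (`mrcost.individual`): non-linear MR by
  residual-exposure stratification into quantiles with local average
  causal effects (LACE) and fractional-polynomial/quadratic/trend shape
  tests; within-family fixed-effect IV with family-clustered errors
  (removes dynastic bias); gene-by-environment interaction MR; and the
  conventional OLS / gamma-GLM comparators.
* **Association layer** (`mrcost.assoc`): vectorised per-SNP regressions,
  GWAS-summary allele harmonization (flips, palindromes, triallelics),
  greedy LD clumping (R² < 0.001 within 10,000 kb by default), weighted
  allele scores, first-stage F and covariate-balance diagnostics.
* **Simulator** (`mrcost.simulate`): cohorts with 79 independent SNPs
  jointly explaining 1.74 % of BMI variance (mean 27.4, SD 4.6), an
  unobserved confounder, two-part zero-inflated gamma costs (≈55 %
  positive, mean ≈ £479/person-year) whose conditional mean is exactly
  linear in the exposure, named pleiotropy presets, and sibling families
  with Mendelian transmission, assortative mating and dynastic effects.

Estimators follow the statsmodels idiom: a model object built from data,
`fit()` returning a results object with `beta`, `se`, `pval`,
heterogeneity diagnostics and `summary()`.

## Worked example

```python
import pandas as pd
from mrcost import (IVW, MREgger, PenalizedWeightedMedian, StructuralParams,
                    default_bmi_panel, make_two_sample_summaries,
                    simulate_unrelated_cohort)

panel = default_bmi_panel(seed=0)                      # 79 BMI-like SNPs
params = StructuralParams(beta=20.0)                   # truth: £20 per kg/m²
exposure_cohort = simulate_unrelated_cohort(panel, params, 100_000, seed=1)
outcome_cohort = simulate_unrelated_cohort(panel, params, 100_000, seed=2,
                                           id_start=100_000)
summ = make_two_sample_summaries(exposure_cohort, outcome_cohort)

print(IVW(summ).fit("multiplicative_random").summary())
```

prints (reproducibly):

```
IVW-RE
==========================================================
causal effect        22.1473  (£ per exposure unit)
std error             3.9763   95% CI [14.354, 29.941]
p-value             2.55e-08   instruments: 79
Cochran Q             64.760   df 78, p 0.8583
```

The point estimate recovers the £20 truth to within about half a
standard error, and the Q p-value of 0.86 correctly reports no
pleiotropy-driven heterogeneity in this no-pleiotropy simulation.
(`RAPS(summ).fit()` gives £22.95 here; RAPS matters most when the
instruments are weaker than at this 100k-per-sample scale, where the
no-measurement-error approximation attenuates the ratio estimators —
see `docs/methods.md`.) A back-of-the-envelope
policy projection then prices a population-wide one-unit BMI shift:

```python
from mrcost import policy_cost_projection
policy_cost_projection(50_000_000, 1.0, 18.85).total_cost  # → £942,500,000
```

A full simulate→harmonize→estimate→report run, with forest/scatter plot
data and a versioned JSON summary, is one call
(`mrcost.run_pipeline(PipelineConfig(...))`) or one shell command:

```bash
mrcost report --seed 1 --out-dir results/demo
```

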