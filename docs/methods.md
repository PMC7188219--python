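# Methods

## Structural model

The simulator and estimators share one data-generating story. For
individual *i* with dosages G_ij ∈ {0,1,2} at J independent bi-allelic
SNPs in Hardy–Weinberg proportions:

    X_i = μ_X + Σ_j γ_j (G_ij − 2p_j) + a_U·U_i + ε_i            (exposure, kg/m²)
    E[Y_i | X, G, U] = μ_Y + β·(X_i − μ_X) + Σ_j α_j (G_ij − 2p_j) + b_U·U_i   (cost, £/person-year)

U is a hidden standard-normal confounder; γ_j are per-allele exposure
effects; α_j are direct (horizontal-pleiotropy) effects that bypass the
exposure. With all α_j = 0, the exclusion restriction holds and any valid
IV estimator identifies β; the reduced-form SNP–outcome effect is then
Γ_j = β·γ_j, which the two-sample ratio estimators exploit.

### Two-part cost outcome

Hospital costs are zero-inflated and right-skewed. Writing η_i for the
centered cost linear predictor above, the simulator draws

    P(Y_i = 0) = logistic(z₀ + z₁·η̃_i)        (η̃ standardized within cohort)
    Y_i | Y_i > 0 ~ Gamma(shape k, mean μ_i / (1 − P(Y_i = 0)))
    μ_i = max(floor, μ_Y + η_i)

so that E[Y_i | X, G, U] = μ_i exactly. The marginal effect of the
exposure on expected cost is therefore exactly β despite the zero mass
and the skew — the property that makes parameter recovery testable. The
floor (£1) binds for ~6×10⁻⁶ of individuals at default parameters, and
the standardization of η̃ uses the realized cohort, both documented
approximations. An optional quadratic term β_q·((X−μ_X)² − σ_X²) bends
the exposure–cost relationship for the non-linearity analyses.

### Default calibration

| Parameter | Default | Unit / meaning |
|---|---|---|
| J (SNPs) | 79 | independent instruments, eaf ~ U(0.05, 0.5) |
| variance explained | 0.0174 | share of exposure variance from the SNP set (HWE) |
| μ_X, σ_X | 27.4, 4.6 | exposure mean and SD (kg/m²) |
| β | 20 | £ per kg/m² per person-year (simulation truth) |
| a_U, b_U | 2 kg/m², £60 | confounder loadings (OLS bias ≈ +£5.7) |
| z₀, z₁ | logit(0.45), −0.3 | zero-cost intercept/slope (≈45 % zeros) |
| k (gamma shape) | 1.0 | exponential-like positive costs; μ_Y = £479 ⇒ overall median ≈ £75–88 |
| dynastic effect | 0 (preset: 10) | £ per unit of mid-parental allele score |
| mate correlation | 0 | exposure correlation between parents |

γ magnitudes are drawn half-normal and rescaled so the panel hits the
variance-explained target exactly under HWE; empirical regression R²
then lands within sampling error of 1.74 % at biobank-scale n.

Pleiotropy presets set α: `none`; `balanced` (α ~ N(0, 10), InSIDE
holds); `directional` (40 % of SNPs get α ~ |N(20, 5)| £/allele, drawn
independently of γ so InSIDE holds — magnitudes fixed by a power
calculation so the MR-Egger intercept test has >80 % power at the
scaled study sizes below); `confounder-mediated` (α ∝ γ plus noise,
violating InSIDE; used for reporting, not asserted unbiased).

Families: two parents drawn as unrelateds (optionally rank-matched on
exposure to a target mate correlation), two offspring by Mendelian
transmission (each parental allele passed with probability dosage/2).
Offspring cost adds dynastic_effect × mid-parental allele score — a
family-constant term, annihilated by family demeaning. Deprivation is
shared within family; other covariates are individual.

## Estimators and numerical choices

* **Ratio/IVW/Egger.** Ratio standard errors use the first-order delta
  method under the no-measurement-error (NOME) convention σ_Y/|γ̂|
  (second-order available behind a flag). IVW equals no-intercept WLS of
  Γ̂ on γ̂ with weights σ_Y⁻²; random effects are multiplicative,
  se × √max(1, Q/(J−1)), never below fixed effects. MR-Egger re-orients
  γ̂ positive, fits WLS with intercept, and inflates by
  √max(1, Q/(J−2)). All p-values are two-sided normal except Q
  (upper-tail χ²).
* **Penalized weighted median.** Ratios sorted (stable, ties keep SNP
  order); estimate interpolates the cumulative standardized weight at
  50 %. Penalty: weight × min(1, 20·p_j) with p_j the upper-χ²₁
  probability of the SNP's Q contribution at the unpenalized estimate.
  Standard errors by parametric bootstrap of (γ̂, Γ̂), 1,000 draws by
  default, seeded; draws are location-scale so monetary-unit
  equivariance is exact.
* **Weighted mode.** Gaussian kernel, inverse-variance weights,
  bandwidth = factor × 0.9·min(sd, IQR/1.349)·J^(−1/5). The maximizer
  is located by evaluating the density at the ratio points and refining
  on a 512-point grid spanning ±3 bandwidths around the best candidate;
  a single global grid over the full ratio range loses the bulk of the
  density to discretization whenever one near-zero γ̂ produces a wild
  ratio, which is exactly the weak-instrument regime where the mode is
  otherwise attractive. Zero spread falls back to the common ratio.
* **RAPS.** β̂ maximizes ℓ(β) = −½Σ(Γ̂−βγ̂)²/(σ_Y²+β²σ_X²) by bounded
  scalar optimization bracketing the IVW start. The standard error is
  the estimating-equation sandwich √(Σψ_j²)/|Σψ'_j| from the per-SNP
  profile scores; the raw observed-curvature error undercovers when the
  profile likelihood departs from quadratic (measured 0.865 vs 0.905
  coverage at weak-instrument conditions), while the sandwich reduces
  to it in the well-identified limit.
* **Per-SNP regressions** are closed-form Frisch–Waugh–Lovell (one
  covariate solve for all SNPs), matching statsmodels to 1e-10. The
  cost outcome uses HC1 robust standard errors by default: the two-part
  gamma cost has variance rising with its mean, and classical errors
  are anti-conservative (Cochran's Q type-I was 6.8–7.0 % vs 5.5 % with
  HC1). Exposure traits stay classical.
* **Harmonization.** Swapped alleles flip the outcome beta and
  complement the frequency; strand complements are recognized;
  palindromic (A/T, C/G) SNPs are kept only when both frequencies are
  on the same side of 0.5 and outside 0.5 ± 0.08 (the window is a
  declared, configurable default — allele labels cannot settle strand
  for palindromes, so frequency is authoritative). Clumping is greedy
  by ascending p-value, snp-id tie-break, symmetric 10,000 kb windows,
  1-based positions.
* **Non-linear MR.** Exposure is residualized on the allele score; the
  cohort is ranked into K = 100 equal strata of residual exposure (ties
  broken by individual id). LACE_k = (stratum score→cost slope, HC1
  se) / (whole-sample score→exposure slope). Because each LACE
  estimates the *derivative* of the outcome function at the stratum
  mean, candidate models are compared on the derivative scale: a linear
  model implies constant LACE; a degree-1 fractional polynomial with
  power p (from {−2,−1,−0.5,0,0.5,1,2,3}, 0 = log) implies
  LACE ∝ x^{p−1}; degree 2 adds a second power (repeated powers
  contribute x^{p−1}·log x). Likelihood ratios use a normal
  approximation with LACE ses treated as known (df 1 for degree 1 vs
  linear, df 2 for degree 2 vs 1; the power search makes these slightly
  approximate, measured type-I ≤ 7 %). The quadratic test is the slope
  of LACE on stratum-mean exposure (the derivative of a squared cost
  term); the trend test is the slope of the per-stratum first-stage on
  mean exposure; Cochran-type Q statistics cover LACE and first-stage
  heterogeneity. The LACE denominator is whole-sample (constancy is
  the first-stage-heterogeneity diagnostic, not an assumption enforced).
* **Family IV.** Two-stage least squares in closed form for the single
  allele-score instrument: β = s̃'ỹ / s̃'x̃ after family demeaning (fixed
  effects) or covariate partialling only (clustered model), with
  family-clustered sandwich errors and a G/(G−1) correction. Verified
  against explicit family-dummy 2SLS.
* **G×E interaction MR.** Per-environment-stratum first-stage and
  reduced-form slopes; WLS of reduced-form on first-stage with
  intercept (weights from reduced-form ses). Slope = causal effect,
  intercept = pleiotropy constant across strata. Declared non-identified
  (error, never silently fitted) when a Cochran test finds no
  first-stage variation at the 5 % level; at least 3 strata required.
* **Comparators.** OLS with HC1 errors; gamma/log-link GLM on the
  positive-cost subset reported as the average marginal effect
  (mean of ∂μ̂_i/∂x) with a delta-method error, validated against a
  central finite difference.

## Study conditions for the Monte-Carlo suites

Simulation sizes are scaled-down emulations of a GWAS-plus-biobank
two-sample design (exposure GWAS n ≈ 339k, outcome cohort n ≈ 307k),
chosen once for the property they probe:

* Parameter recovery: 200 replicates at n = 20,000 per sample, J = 79,
  β = £20. At this scale mean per-SNP F ≈ 4.4 and the NOME-based
  estimators (IVW, median, mode) attenuate by ≈ −£3–4 — a structural
  property of ratio estimators with weak instruments, not an
  implementation artifact (RAPS, which models σ_X, recovers β to
  < £1). The recovery suite reports this honestly: bias bounds fail for
  the NOME estimators at these sizes while interval coverage (0.92 /
  0.985 / 0.955 / 0.905) stays in range.
* Robustness ordering: 60 replicates at 200k/100k (≈ 2:1, matching the
  real design's geometry) under the directional preset. MR-Egger's
  intercept is structurally diluted below I²_GX ≈ 0.9, so smaller sizes
  would test dilution, not detection.
* Q calibration: 500 replicates at 20k/10k (Q's null assumes NOME, so
  the exposure sample leads).
* Dynastic bias: 100 replicates of 5,000 families, dynastic effect £10
  per mid-parental score unit (population bias ≈ +d/2 = £5).
* Non-linearity: 50 replicates at n = 50,000, K = 100; the strong
  quadratic scenario uses β_q = 2.5 £/(kg/m²)², sized for >80 % power.

## What the simulator does and does not emulate

It reproduces the statistical structure MR relies on: independent
instruments with HWE dosages, a calibrated weak-instrument first stage,
confounding that biases OLS but not valid IV, two-part skewed costs with
a known marginal effect, Mendelian transmission and family-level
confounding. It does not emulate linkage disequilibrium (instruments are
exactly independent — clumping is exercised on synthetic LD matrices),
episode-level cost construction, covariate-driven cost structure
(covariates are null by default so balance tests have a true null),
population stratification, or age/cohort-varying genetic effects.
Passing tests therefore demonstrate correctness of the estimators under
the model's assumptions, not robustness to every failure mode of real
biobank data.

## Known limitations

* NOME attenuation at small simulated sizes is reported, not corrected,
  for the ratio estimators; RAPS is the within-package remedy.
* The fractional-polynomial power search slightly inflates the nominal
  likelihood-ratio df; p-values are approximate (measured ≤ 7 % at the
  5 % level).
* Bootstrap standard errors for median/mode are parametric-normal around
  the estimated associations; with very weak instruments they are
  conservative (coverage near the upper band edge).
* The G×E identification check is itself a 5 %-level pretest; borderline
  first-stage variation can be rejected as non-identified.
* Policy projection is exact arithmetic on a constant marginal effect;
  it inherits every limitation of the β it is fed.
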