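"""Synthetic biobank-cohort generator.

Generates cohorts with the statistical structure a Mendelian-randomization
(MR) study of BMI and inpatient hospital costs assumes:

* independent bi-allelic SNPs in Hardy–Weinberg proportions, with
  per-allele effects ``gamma`` on the exposure and optional direct
  (pleiotropic) effects ``alpha`` on the cost outcome;
* a structural model ``X = Σ γ_j G_j + confounding + noise`` and
  ``E[Y | X, G, U] = μ₀ + β·X + Σ α_j G_j + confounding`` with an
  unobserved standard-normal confounder ``U`` loading on both equations;
* a two-part (zero-inflated, right-skewed) cost outcome calibrated so the
  marginal effect of the exposure on expected cost equals ``beta``
  exactly, despite the zeros and the skew;
* optional sibling families with Mendelian transmission, assortative
  mating, and dynastic (parental-genotype) effects on offspring costs.

Defaults mirror a UK-biobank-scale adiposity study: 79 independent SNPs
jointly explaining 1.74 % of exposure variance, exposure mean 27.4 and SD
4.6 kg/m², 55 % of individuals with positive costs, mean cost ≈ £479 and
median ≈ £88 per person-year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import Cohort
from .exceptions import InvalidFrequencyError, OneSampleOverlapWarning

__all__ = [
    "SnpPanel",
    "StructuralParams",
    "default_bmi_panel",
    "simulate_genotypes",
    "simulate_unrelated_cohort",
    "simulate_family_cohort",
    "make_two_sample_summaries",
    "PLEIOTROPY_PRESETS",
]

_BASES = ("A", "C", "G", "T")


@dataclass
class SnpPanel:
    """Per-SNP metadata and true structural parameters for simulation.

    ``gamma`` is the per-allele effect on the exposure (kg/m² per effect
    allele); ``alpha`` is the per-allele direct effect on the outcome
    (£ per allele per person-year) that bypasses the exposure.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    eaf: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        for name in ("snp_id", "chrom", "pos_bp", "effect_allele", "other_allele"):
            setattr(self, name, np.asarray(getattr(self, name)))
        for name in ("eaf", "gamma", "alpha"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(np.unique(self.snp_id)) != len(self.snp_id):
            raise ValueError("snp_id must be unique within a panel")
        if np.any(self.effect_allele == self.other_allele):
            raise ValueError("effect and other allele must differ")
        for arr in (self.effect_allele, self.other_allele):
            if not np.isin(arr, _BASES).all():
                raise ValueError("alleles must be one of A/C/G/T")
        if np.any(self.pos_bp < 1):
            raise ValueError("positions are 1-based: pos_bp >= 1")
        if not np.all(np.isfinite(self.eaf)) or np.any(self.eaf <= 0) or np.any(self.eaf >= 1):
            raise InvalidFrequencyError("eaf must be finite and strictly inside (0, 1)")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    @property
    def dosage_variance(self) -> np.ndarray:
        """Hardy–Weinberg dosage variance 2·eaf·(1−eaf) per SNP."""
        return 2.0 * self.eaf * (1.0 - self.eaf)

    @property
    def genetic_variance(self) -> float:
        """Exposure variance explained by the panel under HWE."""
        return float(np.sum(self.gamma**2 * self.dosage_variance))

    def info_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "effect_allele": self.effect_allele,
                "other_allele": self.other_allele,
                "eaf": self.eaf,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.info_frame()
        out["gamma"] = self.gamma
        out["alpha"] = self.alpha
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SnpPanel":
        return cls(
            snp_id=frame["snp_id"].to_numpy(),
            chrom=frame["chrom"].to_numpy(),
            pos_bp=frame["pos_bp"].to_numpy(),
            effect_allele=frame["effect_allele"].to_numpy(),
            other_allele=frame["other_allele"].to_numpy(),
            eaf=frame["eaf"].to_numpy(),
            gamma=frame["gamma"].to_numpy(),
            alpha=frame["alpha"].to_numpy(),
        )


@dataclass(frozen=True)
class StructuralParams:
    """Parameters of the structural (data-generating) model.

    Attributes
    ----------
    beta : £ per kg/m² per person-year
        Causal (marginal) effect of the exposure on expected cost.
    beta_quadratic : £ per (kg/m²)²
        Optional curvature: adds ``beta_quadratic·(X − mean)²`` to the
        conditional cost mean (zero by default, i.e. a linear effect).
    conf_on_x, conf_on_y
        Loadings of the hidden standard-normal confounder on exposure
        (kg/m² per SD of U) and cost (£ per SD of U).
    zero_prob_intercept, zero_prob_slope
        Logit-scale parameters of P(cost = 0); the slope multiplies the
        standardized cost linear predictor, so a negative slope makes
        high-cost-propensity individuals less likely to have zero cost.
    cost_shape : > 0
        Gamma shape of the positive-cost distribution (1 = exponential).
    cost_mean : £
        Target marginal mean cost per person-year.
    exposure_mean, exposure_sd
        Marginal moments of the exposure (kg/m²).
    snp_variance_share : optional, in (0, 1)
        If set, the panel's gamma vector is rescaled at generation time so
        the SNP set explains exactly this share of exposure variance
        (under HWE); if None the panel's gammas are used as-is.
    dynastic_effect : £ per unit of mid-parental allele score
        Direct effect of parental genotype on offspring cost.
    mate_corr : in [0, 1)
        Exposure correlation between mates (assortative mating).
    gxe_strength
        Multiplies the per-individual genetic effect on exposure by
        ``1 + gxe_strength·(deprivation − 3)/2``, inducing first-stage
        heterogeneity across deprivation quintiles.
    score_pleiotropy : £ per unit of (gamma-weighted) allele score
        Constant direct path from the allele score to cost, used to probe
        pleiotropy-detection by interaction methods.
    """

    beta: float = 20.0
    beta_quadratic: float = 0.0
    conf_on_x: float = 2.0
    conf_on_y: float = 60.0
    zero_prob_intercept: float = float(logit(0.45))
    zero_prob_slope: float = -0.3
    cost_shape: float = 1.0
    cost_mean: float = 479.0
    cost_floor: float = 1.0
    exposure_mean: float = 27.4
    exposure_sd: float = 4.6
    snp_variance_share: float | None = None
    dynastic_effect: float = 0.0
    mate_corr: float = 0.0
    gxe_strength: float = 0.0
    score_pleiotropy: float = 0.0

    def __post_init__(self) -> None:
        if self.cost_shape <= 0:
            raise ValueError("cost_shape must be positive")
        if not 0.0 <= self.mate_corr < 1.0:
            raise ValueError("mate_corr must lie in [0, 1)")
        if self.exposure_sd <= 0:
            raise ValueError("exposure_sd must be positive")
        if self.snp_variance_share is not None and not 0.0 < self.snp_variance_share < 1.0:
            raise ValueError("snp_variance_share must lie in (0, 1)")
        for name in ("beta", "conf_on_x", "conf_on_y", "dynastic_effect", "cost_mean"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------

PLEIOTROPY_PRESETS = ("none", "balanced", "directional", "confounder-mediated")


def default_bmi_panel(
    n_snps: int = 79,
    seed: int | None = 0,
    variance_explained: float = 0.0174,
    exposure_sd: float = 4.6,
    pleiotropy: str = "none",
    prop_invalid: float = 0.4,
    directional_alpha_mean: float = 20.0,
    directional_alpha_sd: float = 5.0,
    balanced_alpha_sd: float = 10.0,
) -> SnpPanel:
    """Draw a BMI-like instrument panel.

    Allele frequencies are Uniform(0.05, 0.5); per-allele exposure effects
    are drawn half-normal and rescaled so the panel jointly explains
    ``variance_explained`` of an exposure with SD ``exposure_sd`` under
    Hardy–Weinberg proportions.

    Pleiotropy presets set the direct SNP→cost effects ``alpha``:

    ``none``
        all alpha are zero (exclusion restriction holds);
    ``balanced``
        zero-mean alpha, independent of gamma (InSIDE holds);
    ``directional``
        a fraction ``prop_invalid`` of SNPs receive positive alpha drawn
        independently of gamma (directional pleiotropy, InSIDE holds);
    ``confounder-mediated``
        alpha proportional to gamma plus noise, emulating pleiotropy that
        acts through a confounder of the exposure (InSIDE violated).
    """
    if pleiotropy not in PLEIOTROPY_PRESETS:
        raise ValueError(f"unknown pleiotropy preset {pleiotropy!r}")
    rng = np.random.default_rng(seed)
    eaf = rng.uniform(0.05, 0.5, n_snps)
    gamma = np.abs(rng.standard_normal(n_snps)) + 0.1
    v = 2 * eaf * (1 - eaf)
    gamma *= np.sqrt(variance_explained * exposure_sd**2 / np.sum(gamma**2 * v))

    if pleiotropy == "none":
        alpha = np.zeros(n_snps)
    elif pleiotropy == "balanced":
        alpha = rng.normal(0.0, balanced_alpha_sd, n_snps)
    elif pleiotropy == "directional":
        alpha = np.zeros(n_snps)
        n_bad = int(round(prop_invalid * n_snps))
        bad = rng.choice(n_snps, size=n_bad, replace=False)
        alpha[bad] = np.abs(rng.normal(directional_alpha_mean, directional_alpha_sd, n_bad))
    else:  # confounder-mediated: alpha tracks instrument strength
        alpha = 120.0 * gamma + rng.normal(0.0, 2.0, n_snps)

    allele_pairs = np.array([("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C")])
    pick = rng.integers(0, len(allele_pairs), n_snps)
    return SnpPanel(
        snp_id=np.array([f"rs{100000 + 13 * k}" for k in range(n_snps)]),
        chrom=1 + (np.arange(n_snps) % 22),
        pos_bp=1_000_000 + 20_000_000 * np.arange(n_snps) // max(n_snps, 1) + 1,
        effect_allele=allele_pairs[pick, 0],
        other_allele=allele_pairs[pick, 1],
        eaf=eaf,
        gamma=gamma,
        alpha=alpha,
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(panel: SnpPanel, n: int, seed=None) -> np.ndarray:
    """Draw an n×J dosage matrix, column j i.i.d. Binomial(2, eaf_j)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    eaf = np.asarray(panel.eaf, dtype=float)
    if not np.all(np.isfinite(eaf)) or np.any(eaf <= 0) or np.any(eaf >= 1):
        raise InvalidFrequencyError("eaf must be finite and strictly inside (0, 1)")
    rng = _as_rng(seed)
    return rng.binomial(2, eaf, size=(n, panel.n_snps)).astype(np.int8)


def _effective_gamma(panel: SnpPanel, params: StructuralParams) -> np.ndarray:
    """Panel gammas, rescaled to the requested variance share if set.

    A panel with all-zero gammas is returned unchanged (null instruments).
    """
    if params.snp_variance_share is None:
        return panel.gamma.copy()
    var_g = panel.genetic_variance
    if var_g == 0:
        return panel.gamma.copy()
    target = params.snp_variance_share * params.exposure_sd**2
    return panel.gamma * np.sqrt(target / var_g)


def _simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Baseline covariates: none enter the structural model by default,
    so allele-score balance tests have a true null to calibrate against."""
    return pd.DataFrame(
        {
            "sex": rng.binomial(1, 0.54, n),  # 1 = female
            "age": rng.normal(56.9, 8.0, n),
            "deprivation": rng.integers(1, 6, n),
            "pc1": rng.standard_normal(n),
            "pc2": rng.standard_normal(n),
        }
    )


def _exposure_from_genetics(
    genetic: np.ndarray,
    genetic_mean: float,
    genetic_var: float,
    u: np.ndarray,
    params: StructuralParams,
    rng: np.random.Generator,
) -> np.ndarray:
    resid_var = params.exposure_sd**2 - genetic_var - params.conf_on_x**2
    if resid_var < 0:
        raise ValueError(
            "exposure variance budget exceeded: genetic variance plus squared "
            "confounder loading exceeds exposure_sd**2"
        )
    noise = rng.normal(0.0, np.sqrt(resid_var), len(u))
    return params.exposure_mean + (genetic - genetic_mean) + params.conf_on_x * u + noise


def _two_part_cost(eta: np.ndarray, params: StructuralParams, rng: np.random.Generator) -> np.ndarray:
    """Two-part cost draw with conditional mean ``cost_mean + eta`` exactly.

    P(zero) is logit-linear in the standardized linear predictor; positive
    costs are gamma with the location shifted so the overall conditional
    mean is preserved, giving a known ground-truth marginal effect despite
    the zero mass and the skew.  The mean is floored at ``cost_floor`` (a
    few parts in 10⁶ of individuals at default parameters).
    """
    sd = float(np.std(eta))
    z = (eta - float(np.mean(eta))) / sd if sd > 0 else np.zeros_like(eta)
    p_zero = expit(params.zero_prob_intercept + params.zero_prob_slope * z)
    mu = np.maximum(params.cost_floor, params.cost_mean + eta)
    mu_pos = mu / (1.0 - p_zero)
    positive = rng.uniform(size=len(eta)) >= p_zero
    cost = np.zeros(len(eta))
    k = params.cost_shape
    cost[positive] = rng.gamma(k, mu_pos[positive] / k)
    return cost


def _cost_linear_predictor(
    cohort_exposure: np.ndarray,
    genotypes: np.ndarray,
    u: np.ndarray,
    panel: SnpPanel,
    gamma_eff: np.ndarray,
    params: StructuralParams,
    extra: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Centered linear predictor of the conditional cost mean."""
    x_c = cohort_exposure - params.exposure_mean
    eta = params.beta * x_c
    if params.beta_quadratic != 0.0:
        eta = eta + params.beta_quadratic * (x_c**2 - params.exposure_sd**2)
    if np.any(panel.alpha != 0.0):
        eta = eta + genotypes @ panel.alpha - float(np.sum(panel.alpha * 2 * panel.eaf))
    if params.score_pleiotropy != 0.0:
        score = genotypes @ gamma_eff
        eta = eta + params.score_pleiotropy * (score - float(np.sum(gamma_eff * 2 * panel.eaf)))
    eta = eta + params.conf_on_y * u
    return eta + extra


def simulate_unrelated_cohort(
    panel: SnpPanel,
    params: StructuralParams,
    n: int,
    seed=None,
    id_start: int = 0,
) -> Cohort:
    """Simulate a cohort of unrelated individuals under the structural model.

    ``id_start`` offsets the individual identifiers so that two calls can
    produce provably disjoint samples for two-sample analyses.
    """
    rng = _as_rng(seed)
    geno = simulate_genotypes(panel, n, rng)
    covs = _simulate_covariates(n, rng)
    gamma_eff = _effective_gamma(panel, params)

    genetic = geno @ gamma_eff
    genetic_mean = float(np.sum(gamma_eff * 2 * panel.eaf))
    genetic_var = float(np.sum(gamma_eff**2 * panel.dosage_variance))
    if params.gxe_strength != 0.0:
        mult = 1.0 + params.gxe_strength * (covs["deprivation"].to_numpy() - 3) / 2.0
        genetic = mult * (genetic - genetic_mean) + genetic_mean

    u = rng.standard_normal(n)
    x = _exposure_from_genetics(genetic, genetic_mean, genetic_var, u, params, rng)
    eta = _cost_linear_predictor(x, geno, u, panel, gamma_eff, params)
    cost = _two_part_cost(eta, params, rng)
    return Cohort(
        genotypes=geno,
        snp_info=panel.info_frame(),
        exposure=x,
        cost=cost,
        covariates=covs,
        confounder=u,
        ids=np.arange(id_start, id_start + n),
    )


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

def _mendelian_offspring(
    father: np.ndarray, mother: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One offspring dosage per family: each parent transmits one of their
    two alleles uniformly at random, independently per SNP."""
    from_father = rng.uniform(size=father.shape) < father / 2.0
    from_mother = rng.uniform(size=mother.shape) < mother / 2.0
    return (from_father.astype(np.int8) + from_mother.astype(np.int8)).astype(np.int8)


def simulate_family_cohort(
    panel: SnpPanel,
    params: StructuralParams,
    n_families: int,
    seed=None,
    offspring_per_family: int = 2,
) -> Cohort:
    """Simulate sibling families (two parents, ``offspring_per_family``
    full siblings each); the returned cohort contains the offspring only.

    Parents are drawn as unrelated individuals; under assortative mating
    (``mate_corr`` > 0) mothers are rank-matched to fathers on exposure.
    Offspring cost includes ``dynastic_effect`` × the mid-parental allele
    score, a family-constant term that biases population-level MR but is
    removed by family fixed effects.
    """
    if n_families < 1:
        raise ValueError("n_families must be at least 1")
    if offspring_per_family < 2:
        raise ValueError("sibling cohorts need at least 2 offspring per family")
    rng = _as_rng(seed)
    gamma_eff = _effective_gamma(panel, params)
    genetic_mean = float(np.sum(gamma_eff * 2 * panel.eaf))
    genetic_var = float(np.sum(gamma_eff**2 * panel.dosage_variance))

    geno_f = simulate_genotypes(panel, n_families, rng)
    geno_m = simulate_genotypes(panel, n_families, rng)
    u_f = rng.standard_normal(n_families)
    u_m = rng.standard_normal(n_families)
    x_f = _exposure_from_genetics(geno_f @ gamma_eff, genetic_mean, genetic_var, u_f, params, rng)
    x_m = _exposure_from_genetics(geno_m @ gamma_eff, genetic_mean, genetic_var, u_m, params, rng)

    if params.mate_corr > 0.0:
        # rank-match mothers to a correlated target built from father exposure
        rho = params.mate_corr
        z_f = (x_f - x_f.mean()) / x_f.std()
        target = rho * z_f + np.sqrt(1 - rho**2) * rng.standard_normal(n_families)
        order = np.empty(n_families, dtype=int)
        order[np.argsort(target, kind="stable")] = np.argsort(x_m, kind="stable")
        geno_m = geno_m[order]
        x_m = x_m[order]

    midparent_score = ((geno_f + geno_m) / 2.0) @ gamma_eff  # family constant

    n = n_families * offspring_per_family
    sib_geno = np.vstack(
        [_mendelian_offspring(geno_f, geno_m, rng) for _ in range(offspring_per_family)]
    )
    family_id = np.tile(np.arange(n_families), offspring_per_family)
    dynastic = params.dynastic_effect * (np.tile(midparent_score, offspring_per_family) - genetic_mean)

    covs = _simulate_covariates(n, rng)
    # deprivation is a parental-environment variable: share it within family
    dep_fam = rng.integers(1, 6, n_families)
    covs["deprivation"] = dep_fam[family_id]

    genetic = sib_geno @ gamma_eff
    u = rng.standard_normal(n)
    x = _exposure_from_genetics(genetic, genetic_mean, genetic_var, u, params, rng)
    eta = _cost_linear_predictor(x, sib_geno, u, panel, gamma_eff, params, extra=dynastic)
    cost = _two_part_cost(eta, params, rng)

    order = np.argsort(family_id, kind="stable")
    return Cohort(
        genotypes=sib_geno[order],
        snp_info=panel.info_frame(),
        exposure=x[order],
        cost=cost[order],
        covariates=covs.iloc[order].reset_index(drop=True),
        family_id=family_id[order],
        confounder=u[order],
        ids=np.arange(n),
    )


# ---------------------------------------------------------------------------
# two-sample summary statistics
# ---------------------------------------------------------------------------

def make_two_sample_summaries(
    cohort_exposure: Cohort,
    cohort_outcome: Cohort,
    covariate_names: list[str] | tuple[str, ...] = (),
):
    """Per-SNP exposure associations from one cohort and outcome
    associations from a second, already on a shared allele orientation.

    Returns a :class:`~mrcost.assoc.HarmonizedSummaries`.  Overlapping
    individual ids trigger a warning (sample overlap biases two-sample MR
    toward the confounded observational estimate) but output is still
    produced.
    """
    from .assoc import HarmonizedSummaries, per_snp_regression

    if cohort_exposure.snp_ids != cohort_outcome.snp_ids:
        raise ValueError("the two cohorts must share the same SNP panel")
    overlap = np.intersect1d(cohort_exposure.ids, cohort_outcome.ids)
    if overlap.size:
        warnings.warn(
            f"{overlap.size} individuals appear in both samples; one-sample "
            "overlap biases estimates toward the non-IV association",
            OneSampleOverlapWarning,
            stacklevel=2,
        )
    exp = per_snp_regression(cohort_exposure, "exposure", list(covariate_names))
    out = per_snp_regression(cohort_outcome, "cost", list(covariate_names))
    return HarmonizedSummaries.from_aligned(exp, out)
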