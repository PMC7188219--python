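"""Individual-level MR sensitivity analyses.

Non-linear MR by residual-exposure stratification (quantile-specific
local average causal effects, LACE), within-family fixed-effect IV with
family-clustered errors, gene-by-environment interaction MR, and the
conventional non-IV comparators (OLS and a gamma/log-link GLM reported as
an average marginal effect).

The two-stage-least-squares core is implemented in closed form for a
single instrument (ratio of reduced-form to first-stage associations on
partialled-out data), which keeps an exact algebraic oracle available for
testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort
from .estimators import MRResults
from .exceptions import WeakInteractionError

__all__ = [
    "StratumEstimate",
    "NonlinearResult",
    "FamilyIVResult",
    "residualize_treatment",
    "stratify_lace",
    "nonlinearity_tests",
    "NonlinearMR",
    "family_fixed_effect_iv",
    "clustered_iv",
    "gxe_interaction_mr",
    "conventional_estimates",
]

FRACPOLY_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)  # 0 denotes log


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class StratumEstimate:
    """Quantile-specific local average causal effect."""

    stratum_index: int  # 1..K
    mean_exposure: float  # kg/m²
    lace: float  # £ per exposure unit
    se: float
    n_stratum: int
    first_stage: float = np.nan  # stratum-specific score→exposure slope
    first_stage_se: float = np.nan


@dataclass
class NonlinearResult:
    """Stratified LACE estimates and shape-of-relationship tests."""

    strata: list[StratumEstimate]
    fracpoly_d1_vs_linear_pval: float
    fracpoly_d2_vs_d1_pval: float
    quadratic_pval: float
    trend_pval: float
    first_stage_heterogeneity_pval: float
    lace_heterogeneity_pval: float = np.nan

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": [s.stratum_index for s in self.strata],
                "mean_exposure": [s.mean_exposure for s in self.strata],
                "lace": [s.lace for s in self.strata],
                "se": [s.se for s in self.strata],
                "n": [s.n_stratum for s in self.strata],
            }
        )


@dataclass
class FamilyIVResult:
    """Allele-score IV estimate from a sibling design."""

    beta: float
    se: float  # family-clustered
    pval: float
    n_individuals: int
    n_families: int
    used_fixed_effects: bool


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _simple_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and se of y on x with intercept (closed form)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("regressor is constant")
    beta = float(xc @ y) / sxx
    resid = y - y.mean() - beta * xc
    sigma2 = float(resid @ resid) / (n - 2)
    return beta, float(np.sqrt(sigma2 / sxx))


def _grouped_slopes(
    x: np.ndarray, y: np.ndarray, offsets: np.ndarray, robust: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group OLS slope and se of y on x, groups given by offsets into
    the (already grouped) arrays.  Vectorized with ``np.add.reduceat``.

    ``robust=True`` returns HC1 sandwich standard errors, appropriate for
    the skewed cost outcome whose variance rises with its mean.
    """
    red = np.add.reduceat
    n = np.diff(np.append(offsets, len(x))).astype(float)
    counts = n.astype(int)
    xc = x - np.repeat(red(x, offsets) / n, counts)
    yc = y - np.repeat(red(y, offsets) / n, counts)
    sxx = red(xc * xc, offsets)
    sxy = red(xc * yc, offsets)
    slope = sxy / sxx
    if robust:
        resid = yc - np.repeat(slope, counts) * xc
        meat = red(xc * xc * resid * resid, offsets)
        se = np.sqrt(n / (n - 2) * meat) / sxx
    else:
        syy = red(yc * yc, offsets)
        ssr = np.maximum(syy - slope**2 * sxx, 0.0)
        se = np.sqrt(ssr / (n - 2) / sxx)
    return slope, se


# ---------------------------------------------------------------------------
# non-linear MR
# ---------------------------------------------------------------------------

def residualize_treatment(cohort: Cohort, score: np.ndarray) -> np.ndarray:
    """Exposure minus its fitted value from a regression on the allele
    score — the exposure a (hypothetical) individual would have with no
    exposure-increasing alleles, up to a constant.  Orthogonal to the
    score by construction."""
    score = np.asarray(score, float)
    if score.std() == 0:
        raise ValueError("score is constant; residualization undefined")
    slope, _ = _simple_slope(score, cohort.exposure)
    fitted = cohort.exposure.mean() + slope * (score - score.mean())
    return cohort.exposure - fitted


def stratify_lace(
    cohort: Cohort,
    score: np.ndarray,
    residual: np.ndarray | None = None,
    K: int = 100,
) -> list[StratumEstimate]:
    """Quantile-stratified local average causal effects.

    Individuals are ranked into K equal-size strata of residual exposure
    (ties broken by individual id, stable).  Within stratum k the LACE is
    the stratum-specific score→cost association divided by the
    whole-sample score→exposure association, with a delta-method standard
    error on the numerator (denominator constancy is a diagnostic, tested
    via :func:`nonlinearity_tests`).
    """
    if cohort.n < 10 * K:
        raise ValueError(
            f"n={cohort.n} too small for K={K} strata (need n >= 10K; use a smaller K)"
        )
    score = np.asarray(score, float)
    if residual is None:
        residual = residualize_treatment(cohort, score)
    order = np.lexsort((cohort.ids, residual))
    offsets = (np.arange(K) * cohort.n) // K  # equal sizes when K | n

    s_sorted = score[order]
    y_sorted = cohort.cost[order]
    x_sorted = cohort.exposure[order]
    num, num_se = _grouped_slopes(s_sorted, y_sorted, offsets, robust=True)
    first, first_se = _grouped_slopes(s_sorted, x_sorted, offsets)
    denom, _ = _simple_slope(score, cohort.exposure)
    if denom == 0:
        raise ValueError("whole-sample score-exposure association is zero")

    sizes = np.diff(np.append(offsets, cohort.n))
    mean_x = np.add.reduceat(x_sorted, offsets) / sizes
    return [
        StratumEstimate(
            stratum_index=k + 1,
            mean_exposure=float(mean_x[k]),
            lace=float(num[k] / denom),
            se=float(num_se[k] / abs(denom)),
            n_stratum=int(sizes[k]),
            first_stage=float(first[k]),
            first_stage_se=float(first_se[k]),
        )
        for k in range(K)
    ]


def _fp_terms(x: np.ndarray, power: float) -> np.ndarray:
    return np.log(x) if power == 0.0 else x**power


def _wls_loglik(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> float:
    """Gaussian log-likelihood (up to a constant) of a WLS fit with the
    LACE standard errors treated as known."""
    fit = sm.WLS(y, X, weights=w).fit()
    return float(-0.5 * np.sum(w * fit.resid**2))


def nonlinearity_tests(strata: list[StratumEstimate]) -> NonlinearResult:
    """Meta-regression shape tests on the stratum LACE estimates.

    Each LACE estimates the *derivative* of the exposure–outcome
    function at the stratum's mean exposure, so candidate outcome models
    are fitted and compared on the derivative scale:

    * a linear outcome model implies a constant LACE (intercept-only
      meta-regression);
    * a degree-1 fractional polynomial α + β₁xᵖ, p from
      {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 = log), implies
      LACE ∝ x^{p−1};
    * a degree-2 fractional polynomial adds a second power (repeated
      powers contribute an x^{p−1}·log x term).

    Best models are compared by likelihood-ratio χ² (df 1 for degree 1
    vs linear, df 2 for degree 2 vs degree 1) under a normal
    approximation with the LACE standard errors treated as known.  The
    quadratic test is the significance of the squared cost-model term,
    i.e. of the slope of LACE on mean exposure; the trend test is the
    slope p-value of the per-stratum instrument→exposure association on
    mean exposure.  Heterogeneity p-values for the LACE set and the
    first-stage estimates come from Cochran-type Q statistics.
    """
    ok = [s for s in strata if np.isfinite(s.se) and s.se > 0]
    if len(ok) < 10:
        raise ValueError("need at least 10 strata with finite standard errors")
    x = np.array([s.mean_exposure for s in ok])
    y = np.array([s.lace for s in ok])
    w = np.array([1.0 / s.se**2 for s in ok])
    if np.any(x <= 0):
        raise ValueError("fractional powers need strictly positive mean exposures")

    ones = np.ones_like(x)
    ll_linear = _wls_loglik(y, ones[:, None], w)  # constant derivative

    ll_d1 = -np.inf
    for p in FRACPOLY_POWERS:
        ll = _wls_loglik(y, _fp_terms(x, p - 1.0)[:, None], w)
        ll_d1 = max(ll_d1, ll)
    ll_d2 = -np.inf
    for i, p1 in enumerate(FRACPOLY_POWERS):
        t1 = _fp_terms(x, p1 - 1.0)
        for p2 in FRACPOLY_POWERS[i:]:
            t2 = t1 * np.log(x) if p2 == p1 else _fp_terms(x, p2 - 1.0)
            ll = _wls_loglik(y, np.column_stack([t1, t2]), w)
            ll_d2 = max(ll_d2, ll)

    p_d1 = float(stats.chi2.sf(max(0.0, 2 * (ll_d1 - ll_linear)), 1))
    p_d2 = float(stats.chi2.sf(max(0.0, 2 * (ll_d2 - ll_d1)), 2))

    quad = sm.WLS(y, np.column_stack([ones, x]), weights=w).fit()
    quadratic_pval = float(2 * stats.norm.sf(abs(quad.params[1] / quad.bse[1])))
    fs_all = np.array([s.first_stage for s in ok])
    fs_w_all = 1.0 / np.array([s.first_stage_se for s in ok]) ** 2
    trend = sm.WLS(fs_all, np.column_stack([ones, x]), weights=fs_w_all).fit()
    trend_pval = float(2 * stats.norm.sf(abs(trend.params[1] / trend.bse[1])))

    fs = np.array([s.first_stage for s in ok])
    fs_se = np.array([s.first_stage_se for s in ok])
    fs_w = 1.0 / fs_se**2
    fs_bar = float(np.sum(fs_w * fs) / np.sum(fs_w))
    q_fs = float(np.sum(fs_w * (fs - fs_bar) ** 2))
    first_stage_het = float(stats.chi2.sf(q_fs, len(ok) - 1))

    ybar = float(np.sum(w * y) / np.sum(w))
    q_lace = float(np.sum(w * (y - ybar) ** 2))
    lace_het = float(stats.chi2.sf(q_lace, len(ok) - 1))

    return NonlinearResult(
        strata=list(strata),
        fracpoly_d1_vs_linear_pval=p_d1,
        fracpoly_d2_vs_d1_pval=p_d2,
        quadratic_pval=quadratic_pval,
        trend_pval=trend_pval,
        first_stage_heterogeneity_pval=first_stage_het,
        lace_heterogeneity_pval=lace_het,
    )


class NonlinearMR:
    """Model-style wrapper: stratified LACE plus shape tests in one fit."""

    def __init__(self, cohort: Cohort, score: np.ndarray, K: int = 100):
        self.cohort = cohort
        self.score = np.asarray(score, float)
        self.K = K

    def fit(self) -> NonlinearResult:
        residual = residualize_treatment(self.cohort, self.score)
        strata = stratify_lace(self.cohort, self.score, residual, K=self.K)
        return nonlinearity_tests(strata)


# ---------------------------------------------------------------------------
# within-family IV
# ---------------------------------------------------------------------------

def _partial_out(z: np.ndarray, *arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    """Residualize each array on the column block z (via lstsq)."""
    if z.shape[1] == 0:
        return arrays
    coef, *_ = np.linalg.lstsq(z, np.column_stack(arrays), rcond=None)
    resid = np.column_stack(arrays) - z @ coef
    return tuple(resid[:, i] for i in range(resid.shape[1]))


def _cluster_iv(
    y: np.ndarray, x: np.ndarray, s: np.ndarray, clusters: np.ndarray
) -> tuple[float, float]:
    """Just-identified IV slope with family-clustered sandwich se.

    β = (s'y)/(s'x); se² = G/(G−1) · Σ_f (Σ_{i∈f} s_i ê_i)² / (s'x)².
    Inputs must already be demeaned/partialled.
    """
    den = float(s @ x)
    if den == 0:
        raise ValueError("first-stage association is zero; IV undefined")
    beta = float(s @ y) / den
    e = y - beta * x
    order = np.argsort(clusters, kind="stable")
    h = s[order] * e[order]
    _, starts = np.unique(clusters[order], return_index=True)
    per_fam = np.add.reduceat(h, starts)
    g = len(per_fam)
    meat = float(np.sum(per_fam**2)) * (g / (g - 1) if g > 1 else 1.0)
    return beta, float(np.sqrt(meat) / abs(den))


def _prep_family(cohort: Cohort, condition_on) -> tuple[np.ndarray, Cohort]:
    if cohort.family_id is None:
        raise ValueError("cohort has no family identifiers")
    return np.asarray(cohort.family_id), cohort


def family_fixed_effect_iv(
    cohort: Cohort, score: np.ndarray, condition_on: tuple[str, ...] = ("sex",)
) -> FamilyIVResult:
    """Within-family allele-score IV: two-stage least squares on
    family-demeaned data with family-clustered standard errors.

    Demeaning absorbs the family fixed effect, removing any
    family-constant influence on costs — dynastic effects of parental
    genotype in particular.  Families reduced to fewer than two members
    are dropped.
    """
    fam, cohort = _prep_family(cohort, condition_on)
    score = np.asarray(score, float)
    ids, counts = np.unique(fam, return_counts=True)
    keep = np.isin(fam, ids[counts >= 2])
    if not keep.any():
        raise ValueError("all families are singletons; fixed effects not estimable")
    fam_k = fam[keep]
    y, x, s = cohort.cost[keep], cohort.exposure[keep], score[keep]
    covs = [np.asarray(cohort.covariates[c], float)[keep] for c in condition_on]

    # within-family demeaning
    order = np.argsort(fam_k, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    _, starts, counts_k = np.unique(fam_k[order], return_index=True, return_counts=True)

    def demean(v: np.ndarray) -> np.ndarray:
        vs = v[order]
        means = np.add.reduceat(vs, starts) / counts_k
        return (vs - np.repeat(means, counts_k))[inv]

    yd, xd, sd = demean(y), demean(x), demean(s)
    covd = [demean(c) for c in covs]
    if covd:
        yd, xd, sd = _partial_out(np.column_stack(covd), yd, xd, sd)
    beta, se = _cluster_iv(yd, xd, sd, fam_k)
    return FamilyIVResult(
        beta=beta,
        se=se,
        pval=float(2 * stats.norm.sf(abs(beta / se))),
        n_individuals=int(keep.sum()),
        n_families=len(counts_k),
        used_fixed_effects=True,
    )


def clustered_iv(
    cohort: Cohort, score: np.ndarray, condition_on: tuple[str, ...] = ("sex",)
) -> FamilyIVResult:
    """Allele-score IV without the family fixed effect, standard errors
    clustered at the family level — the comparison model that shows what
    the fixed effect itself contributes."""
    fam, cohort = _prep_family(cohort, condition_on)
    score = np.asarray(score, float)
    z = np.column_stack(
        [np.ones(cohort.n)] + [np.asarray(cohort.covariates[c], float) for c in condition_on]
    )
    y, x, s = _partial_out(z, cohort.cost, cohort.exposure, score)
    beta, se = _cluster_iv(y, x, s, fam)
    return FamilyIVResult(
        beta=beta,
        se=se,
        pval=float(2 * stats.norm.sf(abs(beta / se))),
        n_individuals=cohort.n,
        n_families=len(np.unique(fam)),
        used_fixed_effects=False,
    )


# ---------------------------------------------------------------------------
# gene-by-environment interaction MR
# ---------------------------------------------------------------------------

def gxe_interaction_mr(
    cohort: Cohort,
    score: np.ndarray,
    env: str = "deprivation",
    het_alpha: float = 0.05,
) -> MRResults:
    """MR identified by environment-driven variation in instrument strength.

    Per environment stratum l the first-stage (score→exposure) and
    reduced-form (score→cost) slopes are estimated; a weighted regression
    of reduced-form on first-stage across strata then recovers the causal
    effect as its slope and any constant pleiotropic effect of the score
    as its intercept — valid when pleiotropy does not differ between
    subgroups.  The model is rejected as non-identified when the
    first-stage shows no detectable variation across strata (Cochran-type
    test at ``het_alpha``).
    """
    score = np.asarray(score, float)
    env_vals = np.asarray(cohort.covariates[env])
    levels = np.unique(env_vals)
    if len(levels) < 3:
        raise ValueError(
            "need at least 3 environment strata to fit slope and intercept with residual df"
        )
    first, first_se, reduced, reduced_se = [], [], [], []
    for lev in levels:
        m = env_vals == lev
        b1, se1 = _simple_slope(score[m], cohort.exposure[m])
        b2, se2 = _simple_slope(score[m], cohort.cost[m])
        first.append(b1)
        first_se.append(se1)
        reduced.append(b2)
        reduced_se.append(se2)
    first = np.array(first)
    first_se = np.array(first_se)
    reduced = np.array(reduced)
    reduced_se = np.array(reduced_se)

    w_fs = 1.0 / first_se**2
    fs_bar = float(np.sum(w_fs * first) / np.sum(w_fs))
    q_fs = float(np.sum(w_fs * (first - fs_bar) ** 2))
    p_het = float(stats.chi2.sf(q_fs, len(levels) - 1))
    if p_het >= het_alpha:
        raise WeakInteractionError(
            f"no detectable first-stage variation across {env} strata "
            f"(heterogeneity p = {p_het:.3f}); interaction instrument is not relevant"
        )

    w = 1.0 / reduced_se**2
    X = np.column_stack([np.ones(len(levels)), first])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * reduced))
    cov = np.linalg.inv(xtwx)
    resid = reduced - X @ coef
    q = float(np.sum(w * resid**2))
    q_df = len(levels) - 2
    inter_se = float(np.sqrt(cov[0, 0]))
    return MRResults(
        "GxE-interaction",
        coef[1],
        float(np.sqrt(cov[1, 1])),
        n_snps=len(levels),
        q=q,
        q_df=q_df,
        q_pval=float(stats.chi2.sf(q, q_df)),
        intercept=float(coef[0]),
        intercept_se=inter_se,
        intercept_pval=float(2 * stats.norm.sf(abs(coef[0] / inter_se))),
    )


# ---------------------------------------------------------------------------
# conventional (non-IV) comparators
# ---------------------------------------------------------------------------

def conventional_estimates(
    cohort: Cohort, covariate_names: list[str] | None = None
) -> tuple[MRResults, MRResults | None]:
    """Multivariable-adjusted OLS and gamma/log-link GLM comparators.

    The OLS marginal effect uses heteroskedasticity-robust (HC1) errors.
    The GLM is fitted to the positive-cost subset and reported as the
    average marginal effect (AME): the mean over fitted individuals of
    the derivative of predicted cost with respect to the exposure, with a
    delta-method standard error.  Returns (OLS, GLM) — the GLM entry is
    None when no individual has positive costs.
    """
    covariate_names = list(
        covariate_names if covariate_names is not None else cohort.covariates.columns
    )
    if np.any(cohort.cost < 0):
        raise ValueError("costs must be non-negative")
    X = sm.add_constant(
        np.column_stack(
            [cohort.exposure]
            + [np.asarray(cohort.covariates[c], float) for c in covariate_names]
        )
    )
    ols_fit = sm.OLS(cohort.cost, X).fit(cov_type="HC1")
    b, se = float(ols_fit.params[1]), float(ols_fit.bse[1])
    ols = MRResults(
        "OLS", b, se, n_snps=0,
        pval=float(2 * stats.norm.sf(abs(b / se))) if se > 0 else np.nan,
    )

    pos = cohort.cost > 0
    if not pos.any():
        return ols, None
    Xp = X[pos]
    glm_fit = sm.GLM(
        cohort.cost[pos], Xp, family=sm.families.Gamma(link=sm.families.links.Log())
    ).fit()
    mu = glm_fit.mu
    b_x = glm_fit.params[1]
    ame = float(b_x * np.mean(mu))
    # delta method: d AME / d params_k = b_x·mean(mu·X_k) + 1{k=exposure}·mean(mu)
    grad = b_x * (Xp * mu[:, None]).mean(axis=0)
    grad[1] += float(np.mean(mu))
    var = float(grad @ glm_fit.cov_params() @ grad)
    glm = MRResults("GLM-gamma-AME", ame, float(np.sqrt(var)), n_snps=0)
    return ols, glm
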