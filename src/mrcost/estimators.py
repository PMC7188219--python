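"""Summary-data Mendelian-randomization estimators.

Each estimator is a small model class constructed from harmonized per-SNP
summary statistics — the aligned tuples (γ̂_j, σ_Xj, Γ̂_j, σ_Yj) — whose
``fit()`` returns an :class:`MRResults` carrying the causal estimate, its
standard error, p-value and heterogeneity diagnostics:

=========================  ==================================================
:class:`IVW`               inverse-variance-weighted ratio meta-analysis,
                           fixed or multiplicative-random effects
:class:`MREgger`           weighted regression with an intercept estimating
                           average directional pleiotropy (InSIDE)
:class:`PenalizedWeightedMedian`
                           50 %-weight median of ratio estimates, outliers
                           down-weighted by their heterogeneity contribution
:class:`WeightedMode`      maximizer of a weighted kernel density of ratio
                           estimates (zero-modal-pleiotropy assumption)
:class:`RAPS`              profile-score estimator robust to many weak
                           instruments and exposure measurement error
:class:`MultivariableMR`   joint direct effects of two exposures
=========================  ==================================================

Ratio standard errors use the first-order delta method under the
no-measurement-error (NOME) convention, σ_Y/|γ̂|; a second-order option is
available behind a flag.  All p-values are two-sided against the normal
reference except Cochran's Q (upper-tail χ²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import UndefinedHeterogeneityError, UndefinedRatioError

__all__ = [
    "RatioEstimate",
    "MRResults",
    "wald_ratio",
    "cochran_q",
    "IVW",
    "MREgger",
    "PenalizedWeightedMedian",
    "WeightedMode",
    "RAPS",
    "MultivariableMR",
    "ivw",
    "mr_egger",
    "penalized_weighted_median",
    "weighted_mode",
    "raps",
    "mvmr",
    "sd_to_natural_units",
]


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class RatioEstimate:
    """Single-SNP Wald ratio with its NOME standard error."""

    ratio: float
    se_ratio: float
    snp_id: str | None = None

    @property
    def weight(self) -> float:
        return self.se_ratio**-2


class MRResults:
    """A causal-effect estimate with uncertainty and diagnostics.

    Attributes mirror statsmodels results: ``beta`` (point estimate, £ per
    exposure unit), ``se``, ``pval``, ``n_snps``, heterogeneity ``q`` with
    ``q_df``/``q_pval``, and for intercept-bearing methods (MR-Egger, the
    gene-by-environment estimator) ``intercept``/``intercept_se``/
    ``intercept_pval``.
    """

    def __init__(
        self,
        method: str,
        beta: float,
        se: float,
        n_snps: int,
        pval: float | None = None,
        q: float | None = None,
        q_df: int | None = None,
        q_pval: float | None = None,
        intercept: float | None = None,
        intercept_se: float | None = None,
        intercept_pval: float | None = None,
        converged: bool = True,
        notes: tuple[str, ...] = (),
    ):
        self.method = method
        self.beta = float(beta)
        self.se = float(se)
        self.n_snps = int(n_snps)
        if pval is None:
            pval = float(2 * stats.norm.sf(abs(self.zvalue))) if se > 0 else np.nan
        self.pval = pval
        self.q = q
        self.q_df = q_df
        self.q_pval = q_pval
        self.intercept = intercept
        self.intercept_se = intercept_se
        self.intercept_pval = intercept_pval
        self.converged = converged
        self.notes = tuple(notes)

    @property
    def zvalue(self) -> float:
        return self.beta / self.se if self.se > 0 else np.inf * np.sign(self.beta)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return (self.beta - z * self.se, self.beta + z * self.se)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "pval": self.pval,
            "n_snps": self.n_snps,
            "q": self.q,
            "q_pval": self.q_pval,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_pval": self.intercept_pval,
        }

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            f"{self.method}",
            "=" * 58,
            f"causal effect   {self.beta:12.4f}  (£ per exposure unit)",
            f"std error       {self.se:12.4f}   95% CI [{lo:.3f}, {hi:.3f}]",
            f"p-value         {self.pval:12.4g}   instruments: {self.n_snps}",
        ]
        if self.q is not None:
            lines.append(f"Cochran Q       {self.q:12.3f}   df {self.q_df}, p {self.q_pval:.4g}")
        if self.intercept is not None:
            lines.append(
                f"intercept       {self.intercept:12.4f}   se {self.intercept_se:.4f}, "
                f"p {self.intercept_pval:.4g}"
            )
        if not self.converged:
            lines.append("WARNING: optimisation did not converge")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<MRResults {self.method}: beta={self.beta:.4g} se={self.se:.4g}>"


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def wald_ratio(
    gamma_hat: float,
    sigma_x: float,
    Gamma_hat: float,
    sigma_y: float,
    snp_id: str | None = None,
    second_order: bool = False,
) -> RatioEstimate:
    """Single-SNP ratio estimate Γ̂/γ̂ with delta-method standard error.

    Under NOME the exposure-side uncertainty is ignored: se = σ_Y/|γ̂|.
    ``second_order=True`` adds the γ̂-uncertainty term of the delta
    expansion (off by default).
    """
    if gamma_hat == 0:
        raise UndefinedRatioError("SNP-exposure association is zero; ratio undefined")
    ratio = Gamma_hat / gamma_hat
    var = sigma_y**2 / gamma_hat**2
    if second_order:
        var += Gamma_hat**2 * sigma_x**2 / gamma_hat**4
    return RatioEstimate(ratio=ratio, se_ratio=float(np.sqrt(var)), snp_id=snp_id)


def _unpack(summaries, gamma, Gamma, se_y, se_x):
    if summaries is not None:
        return summaries.gamma, summaries.Gamma, summaries.se_y, summaries.se_x
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    se_x = np.zeros_like(gamma) if se_x is None else np.asarray(se_x, dtype=float)
    return gamma, Gamma, se_y, se_x


def cochran_q(
    summaries=None,
    beta_ref: float = 0.0,
    *,
    gamma=None,
    Gamma=None,
    se_y=None,
) -> tuple[float, int, float]:
    """Heterogeneity of per-SNP ratios about ``beta_ref``.

    Q = Σ_j w_j (ratio_j − beta_ref)² with w_j = γ̂_j² σ_Yj⁻², referred to
    χ² with J−1 degrees of freedom.
    """
    gamma, Gamma, se_y, _ = _unpack(summaries, gamma, Gamma, se_y, None)
    j = len(gamma)
    if j < 2:
        raise UndefinedHeterogeneityError("heterogeneity needs at least two instruments")
    q = float(np.sum((Gamma - beta_ref * gamma) ** 2 / se_y**2))
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


# ---------------------------------------------------------------------------
# estimator models
# ---------------------------------------------------------------------------

class _SummaryModel:
    """Shared constructor: accepts a HarmonizedSummaries or raw arrays."""

    min_snps = 1

    def __init__(self, summaries=None, *, gamma=None, Gamma=None, se_y=None, se_x=None):
        self.gamma, self.Gamma, self.se_y, self.se_x = _unpack(
            summaries, gamma, Gamma, se_y, se_x
        )
        if np.any(self.se_y <= 0):
            raise ValueError("outcome standard errors must be positive")
        if len(self.gamma) < self.min_snps:
            raise ValueError(
                f"{type(self).__name__} needs at least {self.min_snps} instruments"
            )

    @property
    def n_snps(self) -> int:
        return len(self.gamma)

    def _ratios(self) -> tuple[np.ndarray, np.ndarray]:
        """Ratio estimates and their inverse-variance (NOME) weights."""
        if np.any(self.gamma == 0):
            raise UndefinedRatioError("zero SNP-exposure association among instruments")
        return self.Gamma / self.gamma, self.gamma**2 / self.se_y**2


class IVW(_SummaryModel):
    """Inverse-variance-weighted meta-analysis of per-SNP ratio estimates.

    Numerically identical to the slope of a no-intercept weighted
    regression of Γ̂ on γ̂ with weights σ_Y⁻².  The multiplicative
    random-effects model inflates the fixed-effects standard error by
    √max(1, Q/(J−1)), never shrinking it below fixed effects.
    """

    def fit(self, effects_model: str = "multiplicative_random") -> MRResults:
        if effects_model not in ("fixed", "multiplicative_random"):
            raise ValueError("effects_model must be 'fixed' or 'multiplicative_random'")
        if not np.any(self.gamma != 0):
            raise ValueError("IVW needs at least one SNP with a nonzero exposure effect")
        w = self.gamma**2 / self.se_y**2
        beta = float(np.sum(self.gamma * self.Gamma / self.se_y**2) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        q = q_df = q_pval = None
        if self.n_snps >= 2:
            q, q_df, q_pval = cochran_q(
                beta_ref=beta, gamma=self.gamma, Gamma=self.Gamma, se_y=self.se_y
            )
        label = "IVW-FE"
        if effects_model == "multiplicative_random":
            label = "IVW-RE"
            if q is not None:
                se *= float(np.sqrt(max(1.0, q / q_df)))
        return MRResults(label, beta, se, self.n_snps, q=q, q_df=q_df, q_pval=q_pval)


class MREgger(_SummaryModel):
    """Weighted regression of Γ̂ on γ̂ *with* an intercept.

    The slope is the causal estimate; the intercept estimates the average
    directional pleiotropic effect, consistent when instrument strength is
    independent of the direct effects (InSIDE).  Exposure associations are
    re-oriented to be positive before fitting.  Standard errors use the
    multiplicative random-effects inflation √max(1, Q/(J−2)).
    """

    min_snps = 3

    def fit(self, effects_model: str = "multiplicative_random") -> MRResults:
        sgn = np.where(self.gamma < 0, -1.0, 1.0)
        g = self.gamma * sgn
        G = self.Gamma * sgn
        w = 1.0 / self.se_y**2
        x = np.column_stack([np.ones_like(g), g])
        xtwx = x.T @ (w[:, None] * x)
        xtwy = x.T @ (w * G)
        coef = np.linalg.solve(xtwx, xtwy)
        resid = G - x @ coef
        q = float(np.sum(w * resid**2))
        q_df = self.n_snps - 2
        q_pval = float(stats.chi2.sf(q, q_df))
        cov = np.linalg.inv(xtwx)
        if effects_model == "multiplicative_random" and q_df > 0:
            cov = cov * max(1.0, q / q_df)
        inter_se = float(np.sqrt(cov[0, 0]))
        slope_se = float(np.sqrt(cov[1, 1]))
        return MRResults(
            "MR-Egger",
            coef[1],
            slope_se,
            self.n_snps,
            q=q,
            q_df=q_df,
            q_pval=q_pval,
            intercept=float(coef[0]),
            intercept_se=inter_se,
            intercept_pval=float(2 * stats.norm.sf(abs(coef[0] / inter_se))),
        )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50 %-weight point of the ratio order statistics.

    Cumulative standardized weights s_j = (Σ_{k≤j} w_k − w_j/2)/Σw; the
    estimate interpolates ratio linearly in s at s = 0.5.  Ties in the
    ratios keep input (snp id) order — sorting is stable.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for (B, J) bootstrap arrays."""
    order = np.argsort(ratios, axis=1, kind="stable")
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    c = np.cumsum(w, axis=1)
    s = (c - 0.5 * w) / c[:, -1:]
    out = np.empty(len(r))
    for i in range(len(r)):  # np.interp is 1-D; J is small
        out[i] = np.interp(0.5, s[i], r[i])
    return out


class PenalizedWeightedMedian(_SummaryModel):
    """Weighted median of ratio estimates with heterogeneity penalization.

    Consistent when more than half of the instrument weight comes from
    valid SNPs.  Each SNP's weight w_j = γ̂_j²σ_Yj⁻² is multiplied by
    min(1, 20·p_j), where p_j is the upper-tail χ²₁ probability of the
    SNP's Q contribution at the unpenalized weighted-median estimate, so
    outlying instruments are down-weighted rather than excluded.  The
    standard error comes from a parametric bootstrap of (γ̂, Γ̂).
    """

    min_snps = 3
    penalty_scale = 20.0

    def _point(self, gamma, Gamma, se_y):
        ratios = Gamma / gamma
        w = gamma**2 / se_y**2
        b0 = _weighted_median(ratios, w)
        qj = w * (ratios - b0) ** 2
        w_pen = w * np.minimum(1.0, self.penalty_scale * stats.chi2.sf(qj, 1))
        return _weighted_median(ratios, w_pen)

    def fit(self, n_boot: int = 1000, seed=None) -> MRResults:
        import warnings

        if n_boot < 100:
            warnings.warn("fewer than 100 bootstrap replicates; se will be unstable")
        if np.any(self.gamma == 0):
            raise UndefinedRatioError("zero SNP-exposure association among instruments")
        beta = self._point(self.gamma, self.Gamma, self.se_y)
        rng = np.random.default_rng(seed)
        g = self.gamma + self.se_x * rng.standard_normal((n_boot, self.n_snps))
        G = self.Gamma + self.se_y * rng.standard_normal((n_boot, self.n_snps))
        g = np.where(g == 0, 1e-300, g)
        ratios = G / g
        w = g**2 / self.se_y**2
        b0 = _weighted_median_rows(ratios, w)
        qj = w * (ratios - b0[:, None]) ** 2
        w_pen = w * np.minimum(1.0, self.penalty_scale * stats.chi2.sf(qj, 1))
        boots = _weighted_median_rows(ratios, w_pen)
        se = float(np.std(boots, ddof=1))
        q, q_df, q_pval = cochran_q(
            beta_ref=beta, gamma=self.gamma, Gamma=self.Gamma, se_y=self.se_y
        )
        return MRResults(
            "Penalized weighted median", beta, se, self.n_snps, q=q, q_df=q_df, q_pval=q_pval
        )


class WeightedMode(_SummaryModel):
    """Mode of the weighted empirical density of ratio estimates.

    Consistent when the largest homogeneous cluster of instruments is
    valid (zero modal pleiotropy), even if a majority of SNPs are invalid.
    The density is a Gaussian kernel with inverse-variance weights and a
    modified-Silverman bandwidth h = f·0.9·min(sd, IQR/1.349)·J^{−1/5},
    evaluated on a 512-point grid spanning the ratios ± 3 bandwidths.
    """

    min_snps = 3
    grid_points = 512

    @staticmethod
    def _bandwidth(ratios: np.ndarray, factor: float) -> float:
        iqr = np.subtract(*np.percentile(ratios, [75, 25]))
        spread = min(float(np.std(ratios, ddof=1)), float(abs(iqr)) / 1.349)
        return factor * 0.9 * spread * len(ratios) ** (-0.2)

    @classmethod
    def _mode(cls, ratios: np.ndarray, weights: np.ndarray, factor: float) -> float:
        h = cls._bandwidth(ratios, factor)
        if h <= 0:  # degenerate spread: all ratios effectively identical
            return float(ratios[0])
        # candidate pass at the ratio points keeps the search robust when a
        # wild ratio stretches the range far beyond the grid resolution ...
        cand_dens = np.exp(-0.5 * ((ratios[:, None] - ratios[None, :]) / h) ** 2) @ weights
        center = float(ratios[np.argmax(cand_dens)])
        # ... then a local grid spanning ±3 bandwidths refines the maximizer
        grid = np.linspace(center - 3 * h, center + 3 * h, cls.grid_points)
        dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
        return float(grid[np.argmax(dens)])

    def fit(self, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed=None) -> MRResults:
        import warnings

        if bandwidth_factor <= 0:
            raise ValueError("bandwidth_factor must be positive")
        if n_boot < 100:
            warnings.warn("fewer than 100 bootstrap replicates; se will be unstable")
        ratios, w = self._ratios()
        w = w / np.sum(w)
        beta = self._mode(ratios, w, bandwidth_factor)

        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        chunk = 128
        for start in range(0, n_boot, chunk):
            b = min(chunk, n_boot - start)
            g = self.gamma + self.se_x * rng.standard_normal((b, self.n_snps))
            G = self.Gamma + self.se_y * rng.standard_normal((b, self.n_snps))
            g = np.where(g == 0, 1e-300, g)
            r = G / g
            wb = g**2 / self.se_y**2
            wb = wb / wb.sum(axis=1, keepdims=True)
            for i in range(b):
                boots[start + i] = self._mode(r[i], wb[i], bandwidth_factor)
        se = float(np.std(boots, ddof=1))
        q, q_df, q_pval = cochran_q(
            beta_ref=beta, gamma=self.gamma, Gamma=self.Gamma, se_y=self.se_y
        )
        return MRResults(
            "Weighted mode", beta, se, self.n_snps, q=q, q_df=q_df, q_pval=q_pval
        )


class RAPS(_SummaryModel):
    """Robust adjusted profile score.

    Maximizes the profile log-likelihood
    ℓ(β) = −½ Σ_j (Γ̂_j − βγ̂_j)² / (σ_Yj² + β²σ_Xj²),
    which accounts for measurement error in the exposure associations and
    is therefore unbiased with many weak instruments (assuming pleiotropic
    effects of mean zero).  The standard error is the estimating-equation
    sandwich √(Σψ_j²)/|Σψ'_j| built from the per-SNP profile scores ψ_j,
    which stays honest when the profile likelihood is far from quadratic
    (weak instruments); it reduces to the observed-curvature error in the
    well-identified limit.
    """

    min_snps = 1
    max_iter = 200

    def _profile(self, beta: float) -> float:
        denom = self.se_y**2 + beta**2 * self.se_x**2
        return float(-0.5 * np.sum((self.Gamma - beta * self.gamma) ** 2 / denom))

    def _scores(self, beta: float) -> np.ndarray:
        """Per-SNP profile scores ψ_j(β) = ∂ℓ_j/∂β."""
        r = self.Gamma - beta * self.gamma
        s = self.se_y**2 + beta**2 * self.se_x**2
        return r * self.gamma / s + beta * self.se_x**2 * r**2 / s**2

    def fit(self) -> MRResults:
        if len(self.gamma) >= 2 or np.all(self.se_x == 0):
            start = IVW(gamma=self.gamma, Gamma=self.Gamma, se_y=self.se_y).fit("fixed").beta
        else:
            start = float(self.Gamma[0] / self.gamma[0])
        scale = abs(start) + 10.0 / np.sqrt(np.sum(self.gamma**2 / self.se_y**2)) + 1.0
        res = optimize.minimize_scalar(
            lambda b: -self._profile(b),
            bounds=(start - 50 * scale, start + 50 * scale),
            method="bounded",
            options={"maxiter": self.max_iter, "xatol": 1e-10 * scale},
        )
        beta = float(res.x)
        converged = bool(res.success)
        h = max(1e-6, 1e-5 * scale)
        bread = float(
            np.sum(self._scores(beta + h) - self._scores(beta - h)) / (2 * h)
        )
        meat = float(np.sum(self._scores(beta) ** 2))
        if bread >= 0 or meat <= 0:  # flat or pathological likelihood
            converged = False
            se = np.nan
        else:
            se = float(np.sqrt(meat) / abs(bread))
        q = q_df = q_pval = None
        if self.n_snps >= 2:
            q, q_df, q_pval = cochran_q(
                beta_ref=beta, gamma=self.gamma, Gamma=self.Gamma, se_y=self.se_y
            )
        return MRResults(
            "RAPS", beta, se if np.isfinite(se) else 0.0, self.n_snps,
            pval=float(2 * stats.norm.sf(abs(beta / se))) if np.isfinite(se) and se > 0 else np.nan,
            q=q, q_df=q_df, q_pval=q_pval, converged=converged,
            notes=() if converged else ("profile-likelihood optimisation flagged",),
        )


class MultivariableMR:
    """Joint (direct) effects of two exposures from shared instruments.

    No-intercept weighted regression of Γ̂ on (γ̂_t1, γ̂_t2) with weights
    σ_Y⁻²; each coefficient is the direct causal effect of one exposure
    holding the other fixed.  A rank-deficient design (conditionally weak
    instruments) is rejected.
    """

    def __init__(self, gamma_t1, gamma_t2, Gamma, se_y, names=("t1", "t2")):
        self.x = np.column_stack([np.asarray(gamma_t1, float), np.asarray(gamma_t2, float)])
        self.Gamma = np.asarray(Gamma, dtype=float)
        self.se_y = np.asarray(se_y, dtype=float)
        self.names = tuple(names)
        if len(self.Gamma) < 3:
            raise ValueError("multivariable MR needs at least 3 instruments")

    def fit(self, effects_model: str = "multiplicative_random") -> tuple[MRResults, MRResults]:
        from .exceptions import CollinearInstrumentsError

        w = 1.0 / self.se_y**2
        # a treatment with no instrument associations drops out of the fit
        # (its direct effect is 0 and the other reduces to univariable IVW)
        active = [k for k in range(2) if np.any(self.x[:, k] != 0)]
        if not active:
            raise CollinearInstrumentsError("no nonzero exposure associations")
        x_act = self.x[:, active]
        xtwx = x_act.T @ (w[:, None] * x_act)
        if np.linalg.cond(xtwx) > 1e10:
            raise CollinearInstrumentsError(
                "exposure association vectors are collinear; instruments are "
                "conditionally weak"
            )
        coef_act = np.linalg.solve(xtwx, x_act.T @ (w * self.Gamma))
        cov_act = np.linalg.inv(xtwx)
        coef = np.zeros(2)
        cov = np.zeros((2, 2))
        for i, k in enumerate(active):
            coef[k] = coef_act[i]
            for i2, k2 in enumerate(active):
                cov[k, k2] = cov_act[i, i2]
        resid = self.Gamma - self.x @ coef
        q = float(np.sum(w * resid**2))
        q_df = len(self.Gamma) - len(active)
        q_pval = float(stats.chi2.sf(q, q_df))
        if effects_model == "multiplicative_random" and q_df > 0:
            cov = cov * max(1.0, q / q_df)
        out = tuple(
            MRResults(
                f"MVMR[{self.names[k]}]",
                coef[k],
                float(np.sqrt(cov[k, k])),
                len(self.Gamma),
                q=q,
                q_df=q_df,
                q_pval=q_pval,
            )
            for k in range(2)
        )
        return out


# ---------------------------------------------------------------------------
# functional façade and unit conversion
# ---------------------------------------------------------------------------

def ivw(summaries, effects_model: str = "multiplicative_random") -> MRResults:
    return IVW(summaries).fit(effects_model)


def mr_egger(summaries) -> MRResults:
    return MREgger(summaries).fit()


def penalized_weighted_median(summaries, n_boot: int = 1000, seed=None) -> MRResults:
    return PenalizedWeightedMedian(summaries).fit(n_boot=n_boot, seed=seed)


def weighted_mode(
    summaries, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed=None
) -> MRResults:
    return WeightedMode(summaries).fit(
        bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed
    )


def raps(summaries) -> MRResults:
    return RAPS(summaries).fit()


def mvmr(summaries_t1, summaries_t2, outcome_summaries=None) -> tuple[MRResults, MRResults]:
    """Multivariable MR from two harmonized summary sets sharing SNPs.

    ``summaries_t1``/``summaries_t2`` carry the exposure associations of
    the two traits; outcome associations are taken from ``summaries_t1``
    (or from ``outcome_summaries`` when given as (Gamma, se_y) arrays).
    """
    if list(summaries_t1.snp_ids) != list(summaries_t2.snp_ids):
        raise ValueError("SNP sets must be aligned across exposures")
    if outcome_summaries is None:
        Gamma, se_y = summaries_t1.Gamma, summaries_t1.se_y
    else:
        Gamma, se_y = outcome_summaries
    return MultivariableMR(
        summaries_t1.gamma, summaries_t2.gamma, Gamma, se_y, names=("exposure1", "exposure2")
    ).fit()


def sd_to_natural_units(beta_sd: float, sd: float = 4.6) -> float:
    """Convert an effect per SD of exposure to per natural unit (kg/m²).

    Standard errors scale identically — pass them through the same call.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    return beta_sd / sd
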