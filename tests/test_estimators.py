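"""Estimator suite: closed-form oracles, WLS equivalences, robustness
properties and algebraic invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrcost.estimators import (
    IVW,
    RAPS,
    MREgger,
    MultivariableMR,
    PenalizedWeightedMedian,
    WeightedMode,
    cochran_q,
    sd_to_natural_units,
    wald_ratio,
)
from mrcost.exceptions import (
    CollinearInstrumentsError,
    UndefinedHeterogeneityError,
    UndefinedRatioError,
)


def _simulate_summary(rng, j=20, beta=2.0, gamma_loc=0.3, se_y=0.05, se_x=0.0, alpha=None):
    gamma = gamma_loc + 0.1 * rng.standard_normal(j)
    alpha = np.zeros(j) if alpha is None else alpha
    gh = gamma + se_x * rng.standard_normal(j)
    Gh = beta * gamma + alpha + se_y * rng.standard_normal(j)
    return gh, Gh, np.full(j, se_y), np.full(j, se_x)


class TestWaldRatio:
    def test_formula_arithmetic(self):
        r = wald_ratio(0.25, 0.01, 0.5, 0.1)
        assert r.ratio == pytest.approx(2.0)
        assert r.se_ratio == pytest.approx(0.4)

    def test_zero_outcome_association(self):
        assert wald_ratio(0.2, 0.01, 0.0, 0.1).ratio == 0.0

    def test_zero_exposure_association_rejected(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.5, 0.1)

    def test_second_order_se_exceeds_nome(self):
        first = wald_ratio(0.25, 0.05, 0.5, 0.1)
        second = wald_ratio(0.25, 0.05, 0.5, 0.1, second_order=True)
        assert second.se_ratio > first.se_ratio


class TestIVW:
    def test_single_snp_reduces_to_wald_ratio(self):
        res = IVW(gamma=[0.25], Gamma=[0.5], se_y=[0.1]).fit("fixed")
        assert res.beta == pytest.approx(2.0)
        assert res.se == pytest.approx(0.4)

    def test_equals_no_intercept_wls_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        gh, Gh, se_y, _ = _simulate_summary(rng, se_y=0.08)
        res = IVW(gamma=gh, Gamma=Gh, se_y=se_y).fit("fixed")
        oracle = sm.WLS(Gh, gh[:, None], weights=1.0 / se_y**2).fit()
        assert res.beta == pytest.approx(oracle.params[0], rel=1e-10)
        assert res.se == pytest.approx(oracle.bse[0] / np.sqrt(oracle.mse_resid), rel=1e-10)

    def test_homogeneous_ratios_give_zero_q_equal_ses(self):
        gamma = np.array([0.1, 0.2, 0.3])
        res_f = IVW(gamma=gamma, Gamma=2.0 * gamma, se_y=[0.1, 0.1, 0.1]).fit("fixed")
        res_r = IVW(gamma=gamma, Gamma=2.0 * gamma, se_y=[0.1, 0.1, 0.1]).fit()
        assert res_f.q == pytest.approx(0.0, abs=1e-20)
        assert res_r.se == pytest.approx(res_f.se)

    def test_random_effects_se_never_below_fixed(self):
        rng = np.random.default_rng(2)
        gh, Gh, se_y, _ = _simulate_summary(rng)
        m = IVW(gamma=gh, Gamma=Gh, se_y=se_y)
        assert m.fit("multiplicative_random").se >= m.fit("fixed").se

    def test_orientation_invariance(self):
        rng = np.random.default_rng(3)
        gh, Gh, se_y, _ = _simulate_summary(rng)
        flip = rng.choice([-1.0, 1.0], len(gh))
        a = IVW(gamma=gh, Gamma=Gh, se_y=se_y).fit()
        b = IVW(gamma=gh * flip, Gamma=Gh * flip, se_y=se_y).fit()
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)

    def test_no_instruments_rejected(self):
        with pytest.raises(ValueError):
            IVW(gamma=[], Gamma=[], se_y=[]).fit()


class TestCochranQ:
    def test_zero_under_homogeneity(self):
        gamma = np.array([0.2, 0.25, 0.3])
        q, df, p = cochran_q(beta_ref=2.0, gamma=gamma, Gamma=2.0 * gamma, se_y=[0.1] * 3)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert (df, p) == (2, pytest.approx(1.0))

    def test_displaced_snp_dominates(self):
        gamma = np.full(5, 0.2)
        Gamma = 2.0 * gamma
        Gamma[3] += 10 * 0.1  # displaced by 10 se
        q_all, _, _ = cochran_q(beta_ref=2.0, gamma=gamma, Gamma=Gamma, se_y=[0.1] * 5)
        terms = (Gamma - 2.0 * gamma) ** 2 / 0.1**2
        assert terms[3] == max(terms)
        assert terms[3] / q_all > 0.9

    def test_single_snp_rejected(self):
        with pytest.raises(UndefinedHeterogeneityError):
            cochran_q(beta_ref=0.0, gamma=[0.1], Gamma=[0.2], se_y=[0.1])


class TestMREgger:
    def test_exact_fit_on_collinear_points(self):
        gamma = np.array([0.1, 0.2, 0.3])
        Gamma = 1.5 + 2.0 * gamma  # exact line
        res = MREgger(gamma=gamma, Gamma=Gamma, se_y=[0.1] * 3).fit()
        assert res.beta == pytest.approx(2.0, rel=1e-10)
        assert res.intercept == pytest.approx(1.5, rel=1e-10)
        assert res.q == pytest.approx(0.0, abs=1e-16)

    def test_equals_wls_with_intercept_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        gh, Gh, se_y, _ = _simulate_summary(rng, alpha=np.full(20, 0.5))
        res = MREgger(gamma=gh, Gamma=Gh, se_y=se_y).fit("fixed")
        X = sm.add_constant(gh)
        oracle = sm.WLS(Gh, X, weights=1.0 / se_y**2).fit()
        assert res.intercept == pytest.approx(oracle.params[0], rel=1e-10)
        assert res.beta == pytest.approx(oracle.params[1], rel=1e-10)

    def test_recovers_directional_pleiotropy_under_inside(self):
        """Constant direct effects a0=1.5 with strong instruments: the
        intercept estimates a0 and the slope the causal effect."""
        rng = np.random.default_rng(5)
        slopes, inters = [], []
        for _ in range(200):
            gh, Gh, se_y, _ = _simulate_summary(
                rng, j=30, beta=2.0, gamma_loc=0.6, se_y=0.05, alpha=np.full(30, 1.5)
            )
            res = MREgger(gamma=gh, Gamma=Gh, se_y=se_y).fit()
            slopes.append(res.beta)
            inters.append(res.intercept)
        assert np.mean(inters) == pytest.approx(1.5, abs=3 * np.std(inters) / np.sqrt(200))
        assert np.mean(slopes) == pytest.approx(2.0, abs=3 * np.std(slopes) / np.sqrt(200))

    def test_balanced_pleiotropy_gives_null_intercept(self):
        rng = np.random.default_rng(6)
        inters = []
        for _ in range(100):
            alpha = rng.normal(0, 0.3, 25)
            gh, Gh, se_y, _ = _simulate_summary(rng, j=25, se_y=0.05, alpha=alpha)
            inters.append(MREgger(gamma=gh, Gamma=Gh, se_y=se_y).fit().intercept)
        assert abs(np.mean(inters)) < 3 * np.std(inters) / np.sqrt(100)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            MREgger(gamma=[0.1, 0.2], Gamma=[0.2, 0.4], se_y=[0.1, 0.1])


class TestPenalizedWeightedMedian:
    def test_bruteforce_oracle_on_printed_set(self):
        """Equal weights, ratios (1,2,3,4,100): the plain 50%-weight point
        is the middle ratio 3; the penalized estimate follows from the
        brute-force cumulative-weight computation after the outlier at 100
        loses its weight."""
        from mrcost.estimators import _weighted_median

        gamma = np.ones(5)
        Gamma = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        assert _weighted_median(Gamma / gamma, np.ones(5)) == pytest.approx(3.0)

        # independent brute force of the penalty step at the unpenalized
        # estimate 3: q_j = (r_j-3)^2, w_j* = min(1, 20·P(chi2_1 > q_j))
        r = Gamma.copy()
        w_pen = np.minimum(1.0, 20.0 * stats.chi2.sf((r - 3.0) ** 2, 1))
        s = (np.cumsum(w_pen) - 0.5 * w_pen) / w_pen.sum()
        expected = float(np.interp(0.5, s, r))
        res = PenalizedWeightedMedian(gamma=gamma, Gamma=Gamma, se_y=np.ones(5)).fit(
            n_boot=200, seed=0
        )
        assert res.beta == pytest.approx(expected, rel=1e-10)

    def test_cumulative_weight_interpolation_oracle(self):
        """Unequal weights: brute-force cumulative-weight interpolation."""
        from mrcost.estimators import _weighted_median

        rng = np.random.default_rng(7)
        for _ in range(50):
            r = rng.normal(size=9)
            w = rng.uniform(0.1, 2.0, size=9)
            order = np.argsort(r)
            rs, ws = r[order], w[order]
            s = (np.cumsum(ws) - 0.5 * ws) / ws.sum()
            expected = float(np.interp(0.5, s, rs))
            assert _weighted_median(r, w) == pytest.approx(expected, rel=1e-12)

    def test_identical_ratios_returns_common_value(self):
        gamma = np.array([0.1, 0.2, 0.4])
        res = PenalizedWeightedMedian(gamma=gamma, Gamma=3.0 * gamma, se_y=[0.1] * 3).fit(
            n_boot=300, seed=1
        )
        assert res.beta == pytest.approx(3.0, rel=1e-10)
        assert res.se < 1.0

    def test_robust_to_minority_invalid_instruments(self):
        """40% of SNPs with large positive direct effects: the median stays
        near the truth while IVW is dragged upward."""
        rng = np.random.default_rng(8)
        med, ivw = [], []
        for _ in range(200):
            alpha = np.zeros(30)
            alpha[:12] = 3.0
            gh, Gh, se_y, _ = _simulate_summary(rng, j=30, beta=2.0, se_y=0.05, alpha=alpha)
            med.append(
                PenalizedWeightedMedian(gamma=gh, Gamma=Gh, se_y=se_y)._point(gh, Gh, se_y)
            )
            ivw.append(IVW(gamma=gh, Gamma=Gh, se_y=se_y).fit().beta)
        assert abs(np.mean(med) - 2.0) < 3 * np.std(med) / np.sqrt(200) + 0.05
        assert np.mean(ivw) - 2.0 > 10 * (np.std(ivw) / np.sqrt(200))

    def test_few_bootstrap_draws_warns(self):
        gamma = np.ones(3)
        with pytest.warns(UserWarning):
            PenalizedWeightedMedian(gamma=gamma, Gamma=gamma, se_y=np.ones(3)).fit(
                n_boot=50, seed=0
            )


class TestWeightedMode:
    def test_identical_ratios_returns_common_value(self):
        gamma = np.array([0.1, 0.2, 0.4])
        res = WeightedMode(gamma=gamma, Gamma=2.5 * gamma, se_y=[0.1] * 3).fit(
            n_boot=150, seed=2
        )
        assert res.beta == pytest.approx(2.5, rel=1e-10)

    def test_majority_cluster_wins_grid_oracle(self):
        """6 ratios near 2, 4 near 5: the density maximum sits within 0.2
        of 2, matching an independent grid search."""
        rng = np.random.default_rng(9)
        ratios = np.concatenate([2.0 + 0.05 * rng.standard_normal(6),
                                 5.0 + 0.05 * rng.standard_normal(4)])
        gamma = np.ones(10)
        model = WeightedMode(gamma=gamma, Gamma=ratios, se_y=np.ones(10))
        res = model.fit(n_boot=150, seed=3)
        assert abs(res.beta - 2.0) < 0.2
        # independent grid-search oracle at the same bandwidth
        h = model._bandwidth(ratios, 1.0)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 4096)
        dens = np.exp(-0.5 * ((grid[:, None] - ratios) / h) ** 2).sum(axis=1)
        assert abs(res.beta - grid[np.argmax(dens)]) < 0.05

    def test_bandwidth_scaling_is_continuous(self):
        rng = np.random.default_rng(10)
        gh, Gh, se_y, _ = _simulate_summary(rng, j=15, se_y=0.1)
        model = WeightedMode(gamma=gh, Gamma=Gh, se_y=se_y)
        estimates = [model.fit(bandwidth_factor=f, n_boot=100, seed=4).beta
                     for f in (1.0, 1.1, 1.2, 1.3)]
        steps = np.abs(np.diff(estimates))
        span = np.ptp(Gh / gh)
        assert np.all(steps < 0.25 * span)  # no jumps beyond grid scale


class TestRAPS:
    def test_reduces_to_fixed_ivw_without_measurement_error(self):
        rng = np.random.default_rng(11)
        gh, Gh, se_y, _ = _simulate_summary(rng)
        r = RAPS(gamma=gh, Gamma=Gh, se_y=se_y, se_x=np.zeros(20)).fit()
        i = IVW(gamma=gh, Gamma=Gh, se_y=se_y).fit("fixed")
        assert r.beta == pytest.approx(i.beta, rel=1e-8)

    def test_single_snp_matches_grid_search(self):
        model = RAPS(gamma=[0.3], Gamma=[0.7], se_y=[0.1], se_x=[0.05])
        res = model.fit()
        grid = np.linspace(-5, 10, 200_001)
        ll = -0.5 * (0.7 - grid * 0.3) ** 2 / (0.1**2 + grid**2 * 0.05**2)
        assert res.beta == pytest.approx(grid[np.argmax(ll)], abs=1e-3)

    def test_less_biased_than_ivw_with_weak_instruments(self):
        """Per-SNP F ≈ 5: the profile score corrects the denominator
        attenuation that biases fixed-effects IVW toward zero."""
        rng = np.random.default_rng(12)
        raps_est, ivw_est = [], []
        for _ in range(200):
            gamma = np.full(40, 0.1)
            se_x = np.full(40, 0.045)  # F ≈ (0.1/0.045)² ≈ 5
            gh = gamma + se_x * rng.standard_normal(40)
            Gh = 2.0 * gamma + 0.05 * rng.standard_normal(40)
            raps_est.append(RAPS(gamma=gh, Gamma=Gh, se_y=np.full(40, 0.05), se_x=se_x).fit().beta)
            ivw_est.append(IVW(gamma=gh, Gamma=Gh, se_y=np.full(40, 0.05)).fit().beta)
        assert abs(np.mean(raps_est) - 2.0) < abs(np.mean(ivw_est) - 2.0)


class TestMultivariableMR:
    def test_nested_reduction_to_univariable_ivw(self):
        rng = np.random.default_rng(13)
        gh, Gh, se_y, _ = _simulate_summary(rng)
        g2 = np.zeros_like(gh)  # second exposure has no instrument effects
        res1, res2 = MultivariableMR(gh, g2, Gh, se_y).fit("fixed")
        uni = IVW(gamma=gh, Gamma=Gh, se_y=se_y).fit("fixed")
        assert res1.beta == pytest.approx(uni.beta, rel=1e-10)
        assert res2.beta == 0.0

    def test_matches_wls_oracle_on_hand_system(self):
        import statsmodels.api as sm

        g1 = np.array([0.3, 0.1, 0.2, 0.4])
        g2 = np.array([0.1, 0.3, 0.05, 0.2])
        Gamma = 2.0 * g1 - 1.0 * g2 + np.array([0.01, -0.02, 0.005, 0.0])
        se_y = np.array([0.05, 0.04, 0.06, 0.05])
        res1, res2 = MultivariableMR(g1, g2, Gamma, se_y).fit("fixed")
        oracle = sm.WLS(Gamma, np.column_stack([g1, g2]), weights=1.0 / se_y**2).fit()
        assert res1.beta == pytest.approx(oracle.params[0], rel=1e-10)
        assert res2.beta == pytest.approx(oracle.params[1], rel=1e-10)

    def test_null_second_exposure_recovered(self):
        """Exposure 2 has no direct effect: its coefficient is consistent
        with zero in at least 90% of replicates."""
        rng = np.random.default_rng(14)
        hits = 0
        for _ in range(100):
            g1 = 0.3 + 0.1 * rng.standard_normal(25)
            g2 = 0.2 + 0.1 * rng.standard_normal(25)
            Gamma = 2.0 * g1 + 0.05 * rng.standard_normal(25)
            _, res2 = MultivariableMR(g1, g2, Gamma, np.full(25, 0.05)).fit()
            hits += abs(res2.beta / res2.se) < 2
        assert hits >= 90

    def test_collinear_design_rejected(self):
        g1 = np.array([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(CollinearInstrumentsError):
            MultivariableMR(g1, 2.0 * g1, g1, np.full(4, 0.1)).fit()


class TestUnitConversion:
    @pytest.mark.parametrize("beta_sd,expected", [(9.2, 2.0), (0.0, 0.0), (4.6, 1.0)])
    def test_sd_division(self, beta_sd, expected):
        assert sd_to_natural_units(beta_sd) == pytest.approx(expected)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            sd_to_natural_units(1.0, sd=0.0)


# ---------------------------------------------------------------------------
# algebraic invariants (property-based)
# ---------------------------------------------------------------------------

@st.composite
def summary_sets(draw):
    j = draw(st.integers(4, 12))
    rng = np.random.default_rng(draw(st.integers(0, 2**20)))
    gamma = rng.uniform(0.05, 0.5, j) * rng.choice([-1, 1], j)
    Gamma = 2.0 * gamma + rng.normal(0, 0.1, j)
    se_y = rng.uniform(0.02, 0.2, j)
    return gamma, Gamma, se_y


@settings(max_examples=30, deadline=None, derandomize=True)
@given(summary_sets(), st.sampled_from([0.1, 3.0, 250.0]))
def test_monetary_unit_equivariance(data, c):
    """Rescaling the outcome associations by c rescales every estimator's
    point estimate and standard error by c."""
    gamma, Gamma, se_y = data
    base_m = PenalizedWeightedMedian(gamma=gamma, Gamma=Gamma, se_y=se_y).fit(n_boot=100, seed=5)
    scl_m = PenalizedWeightedMedian(gamma=gamma, Gamma=c * Gamma, se_y=c * se_y).fit(
        n_boot=100, seed=5
    )
    assert scl_m.beta == pytest.approx(c * base_m.beta, rel=1e-9)
    assert scl_m.se == pytest.approx(c * base_m.se, rel=1e-6)
    for model in (IVW, MREgger, RAPS):
        base = model(gamma=gamma, Gamma=Gamma, se_y=se_y).fit()
        scaled = model(gamma=gamma, Gamma=c * Gamma, se_y=c * se_y).fit()
        assert scaled.beta == pytest.approx(c * base.beta, rel=1e-6)
        assert scaled.se == pytest.approx(c * base.se, rel=1e-6)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(summary_sets())
def test_ivw_orientation_invariance_property(data):
    gamma, Gamma, se_y = data
    a = IVW(gamma=gamma, Gamma=Gamma, se_y=se_y).fit()
    b = IVW(gamma=-gamma, Gamma=-Gamma, se_y=se_y).fit()
    assert a.beta == pytest.approx(b.beta, rel=1e-12)
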