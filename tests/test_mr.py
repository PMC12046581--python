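import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from drugtarget_mr.harmonize import HarmonizedSet
from drugtarget_mr.mr import (Z95, bonferroni_classify, difference_test, ivw,
                              mr_egger, recover_p_from_ci, scale_or,
                              simple_median, wald_ratio, weighted_median)


def hset(beta_x, beta_y, se_y, se_x=None):
    beta_x = np.asarray(beta_x, float)
    beta_y = np.asarray(beta_y, float)
    se_y = np.asarray(se_y, float)
    se_x = (np.full_like(beta_x, 0.01) if se_x is None
            else np.asarray(se_x, float))
    ids = [f"s{i}" for i in range(len(beta_x))]
    return HarmonizedSet(ids, beta_x, se_x, beta_y, se_y,
                         np.zeros(len(beta_x), dtype=bool))


FIVE_SNP = hset(beta_x=[0.51, 0.32, 0.18, 0.44, 0.25],
                beta_y=[0.013, 0.004, 0.008, 0.011, 0.002],
                se_y=[0.004, 0.006, 0.005, 0.003, 0.007])

SIX_SNP = hset(beta_x=[0.51, 0.32, 0.18, 0.44, 0.25, 0.38],
               beta_y=[0.021, 0.004, 0.012, 0.011, 0.002, 0.017],
               se_y=[0.004, 0.006, 0.005, 0.003, 0.007, 0.005])


class TestWaldRatio:
    def test_point_and_se(self):
        r = wald_ratio(0.2, 0.05, 0.5)
        assert r.beta == pytest.approx(0.4)
        assert r.se == pytest.approx(0.1)

    def test_null_numerator(self):
        r = wald_ratio(0.0, 0.05, 0.5)
        assert r.beta == 0.0 and r.pval == pytest.approx(1.0)

    def test_joint_sign_flip_invariance(self):
        a = wald_ratio(0.2, 0.05, 0.5)
        b = wald_ratio(-0.2, 0.05, -0.5)
        assert a.beta == b.beta and a.se == b.se

    def test_zero_denominator_is_error(self):
        with pytest.raises(ValueError):
            wald_ratio(0.2, 0.05, 0.0)


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = hset([0.5], [0.2], [0.05])
        r = ivw(h)
        w = wald_ratio(0.2, 0.05, 0.5)
        assert r.method == "wald"
        assert r.beta == w.beta and r.se == w.se

    def test_exact_fit_three_snps(self):
        h = hset([0.2, 0.4, 0.6], [0.1, 0.2, 0.3], [0.05, 0.05, 0.05])
        r = ivw(h)
        assert r.method == "ivw_fixed"  # three variants: fixed effects
        assert r.beta == pytest.approx(0.5)
        assert r.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_against_wls_through_origin_oracle(self):
        """IVW equals weighted regression through the origin (normal equations)."""
        h = FIVE_SNP
        w = 1.0 / h.se_y ** 2
        fit = sm.WLS(h.beta_y, h.beta_x, weights=w).fit()
        r = ivw(h)
        assert r.method == "ivw_mre"  # five variants
        assert r.beta == pytest.approx(fit.params[0], abs=1e-10)
        se_fixed = float(fit.bse[0]) / np.sqrt(fit.scale)
        q = float(fit.ssr)
        assert r.q_stat == pytest.approx(q, abs=1e-10)
        expected_se = se_fixed * max(1.0, np.sqrt(q / (h.n_snps - 1)))
        assert r.se == pytest.approx(expected_se, abs=1e-10)

    def test_mre_se_never_below_fixed(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            h = hset(rng.uniform(0.1, 0.6, n), rng.normal(0, 0.02, n),
                     rng.uniform(0.002, 0.01, n))
            r = ivw(h)
            se_fixed = 1.0 / np.sqrt(np.sum(h.beta_x ** 2 / h.se_y ** 2))
            assert r.se >= se_fixed - 1e-15

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            ivw(hset([], [], []))


class TestMedians:
    def test_simple_median_point(self):
        h = hset([1.0, 1.0, 1.0], [0.1, 0.5, 0.9], [0.05, 0.05, 0.05])
        r = simple_median(h, n_boot=200, seed=1)
        assert r.beta == pytest.approx(0.5)

    def test_constant_ratios(self):
        h = hset([0.2, 0.4, 0.6], [0.06, 0.12, 0.18], [0.05, 0.05, 0.05])
        r = simple_median(h, n_boot=500, seed=1)
        assert r.beta == pytest.approx(0.3)
        assert r.ci_low < 0.3 < r.ci_high

    def test_equal_weights_weighted_equals_simple(self):
        h = hset([0.3, 0.3, 0.3, 0.3, 0.3],
                 [0.03, 0.09, 0.15, 0.06, 0.12],
                 [0.05, 0.05, 0.05, 0.05, 0.05])
        assert weighted_median(h, n_boot=10, seed=0).beta == pytest.approx(
            simple_median(h, n_boot=10, seed=0).beta)

    def test_weighted_median_hand_example(self):
        # weights proportional to (0.6, 0.2, 0.2); ratios 0.1 < 0.5 < 0.9
        bx = np.sqrt([0.6, 0.2, 0.2])
        ratios = np.array([0.1, 0.5, 0.9])
        h = hset(bx, ratios * bx, [1.0, 1.0, 1.0])
        # cumulative mid-weights: 0.3, 0.7, 0.9 -> interpolate r1..r2 at 0.5
        expected = 0.1 + (0.5 - 0.1) * (0.5 - 0.3) / (0.7 - 0.3)
        r = weighted_median(h, n_boot=10, seed=0)
        assert r.beta == pytest.approx(expected)

    def test_dominant_weight_snaps_to_heavy_snp(self):
        bx = np.sqrt([0.9, 0.05, 0.05])
        ratios = np.array([0.5, 0.1, 0.9])
        h = hset(bx, ratios * bx, [1.0, 1.0, 1.0])
        r = weighted_median(h, n_boot=10, seed=0)
        assert abs(r.beta - 0.5) < 0.1

    def test_permutation_invariance(self):
        h = FIVE_SNP
        perm = [3, 0, 4, 1, 2]
        hp = hset(h.beta_x[perm], h.beta_y[perm], h.se_y[perm])
        assert weighted_median(h, n_boot=10, seed=0).beta == pytest.approx(
            weighted_median(hp, n_boot=10, seed=0).beta)

    def test_too_few_instruments(self):
        with pytest.raises(ValueError, match="insufficient"):
            simple_median(hset([0.1, 0.2], [0.1, 0.2], [0.05, 0.05]))


class TestEgger:
    def test_noise_free_exact_fit(self):
        bx = np.array([0.1, 0.25, 0.4, 0.55])
        by = 0.05 + 0.3 * bx
        h = hset(bx, by, [0.01, 0.02, 0.03, 0.01])
        r = mr_egger(h)
        assert r.beta == pytest.approx(0.3, abs=1e-12)
        assert r.egger_intercept == pytest.approx(0.05, abs=1e-12)

    def test_zero_intercept_recovered(self):
        bx = np.array([0.1, 0.25, 0.4])
        h = hset(bx, 0.3 * bx, [0.01, 0.02, 0.03])
        assert mr_egger(h).egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_against_wls_oracle(self):
        h = SIX_SNP
        w = 1.0 / h.se_y ** 2
        x = sm.add_constant(h.beta_x)
        fit = sm.WLS(h.beta_y, x, weights=w).fit()
        r = mr_egger(h)
        assert r.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert r.beta == pytest.approx(fit.params[1], abs=1e-10)
        # statsmodels scale = Q/(n-2) = phi; our SE floors the inflation at 1
        phi = fit.scale
        factor = max(1.0, np.sqrt(phi)) / np.sqrt(phi)
        assert r.se == pytest.approx(float(fit.bse[1]) * factor, abs=1e-10)
        assert r.egger_intercept_se == pytest.approx(
            float(fit.bse[0]) * factor, abs=1e-10)
        assert r.q_stat == pytest.approx(float(fit.ssr), abs=1e-10)

    def test_orients_internally(self):
        # exact Egger fit in the oriented frame; first SNP presented flipped
        bx_o = np.array([0.1, 0.25, 0.4, 0.55])
        by_o = 0.05 + 0.3 * bx_o
        bx, by = bx_o.copy(), by_o.copy()
        bx[0], by[0] = -bx[0], -by[0]
        r = mr_egger(hset(bx, by, [0.01, 0.02, 0.03, 0.01]))
        assert r.beta == pytest.approx(0.3, abs=1e-12)
        assert r.egger_intercept == pytest.approx(0.05, abs=1e-12)

    def test_collinear_design_is_error(self):
        h = hset([0.3, 0.3, 0.3], [0.1, 0.2, 0.3], [0.05, 0.05, 0.05])
        with pytest.raises(ValueError, match="collinear"):
            mr_egger(h)


class TestScaleOr:
    def test_null_beta(self):
        o, lo, hi = scale_or(0.0, 0.01)
        assert o == 1.0
        assert lo == pytest.approx(np.exp(-Z95 * 10 * 0.01))
        assert hi == pytest.approx(np.exp(Z95 * 10 * 0.01))

    def test_per_10_unit_decrease(self):
        o, lo, hi = scale_or(0.1, 0.02, factor=-10)
        assert o == pytest.approx(np.exp(-1.0))
        assert lo < o < hi

    def test_ci_ordered_for_any_factor_sign(self):
        for factor in (-10, 10, -1):
            o, lo, hi = scale_or(0.05, 0.03, factor)
            assert lo < o < hi


class TestRecoverP:
    def test_identity_scale_null(self):
        assert recover_p_from_ci(0.0, -1.0, 1.0, "identity") == pytest.approx(1.0)

    def test_log_scale_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            recover_p_from_ci(-0.5, 0.1, 1.0, "log")

    def test_bad_ci_order(self):
        with pytest.raises(ValueError):
            recover_p_from_ci(0.5, 1.0, 0.1, "identity")

    def test_round_trips_a_wald_interval(self):
        beta, se = 0.12, 0.04
        z = beta / se
        from scipy.stats import norm
        p = 2 * norm.sf(z)
        assert recover_p_from_ci(beta, beta - Z95 * se, beta + Z95 * se,
                                 "identity") == pytest.approx(p, rel=1e-6)


class TestDifferenceTest:
    def test_closed_form_example(self):
        d = difference_test(-0.05, 0.01, -0.03, 0.005)
        assert d.beta_diff == pytest.approx(-0.02)
        assert d.se_diff == pytest.approx(0.011180, abs=1e-6)
        assert d.pval == pytest.approx(0.0736, abs=2e-4)
        assert d.ci_low == pytest.approx(d.beta_diff - Z95 * d.se_diff)

    def test_identical_inputs(self):
        d = difference_test(-0.05, 0.01, -0.05, 0.02)
        assert d.beta_diff == 0.0 and d.pval == pytest.approx(1.0)

    def test_ci_symmetric(self):
        d = difference_test(0.1, 0.03, 0.02, 0.04)
        assert (d.ci_high - d.beta_diff) == pytest.approx(
            d.beta_diff - d.ci_low)


class TestBonferroni:
    def test_thirty_five_tests(self):
        call = bonferroni_classify(0.001, 35)
        assert call.threshold == pytest.approx(0.05 / 35)
        assert call.category == "significant"

    def test_nominal_band(self):
        assert bonferroni_classify(0.01, 35).category == "nominal"

    def test_none(self):
        assert bonferroni_classify(0.2, 35).category == "none"


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_estimators_invariant_to_sign_flip_and_permutation(seed):
    """Joint (beta_x, beta_y) sign flips and SNP order changes leave every
    estimator's point estimate unchanged."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 10))
    bx = rng.uniform(0.1, 0.6, n)
    by = rng.normal(0.01, 0.01, n)
    sy = rng.uniform(0.002, 0.01, n)
    h = hset(bx, by, sy)
    flip = rng.choice([-1.0, 1.0], n)
    perm = rng.permutation(n)
    h2 = hset((bx * flip)[perm], (by * flip)[perm], sy[perm])
    for fn in (ivw, mr_egger):
        assert fn(h).beta == pytest.approx(fn(h2).beta, rel=1e-9)
    assert simple_median(h, 5, 0).beta == pytest.approx(
        simple_median(h2, 5, 0).beta, rel=1e-9)
    assert weighted_median(h, 5, 0).beta == pytest.approx(
        weighted_median(h2, 5, 0).beta, rel=1e-9)
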