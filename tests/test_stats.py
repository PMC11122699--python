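"""Group statistics: effect sizes, equivalence, rank tests, power, screening."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from flankerssp.stats import (
    GroupSummary,
    bootstrap_mean_difference,
    cohens_d,
    cohens_d_from_samples,
    mann_whitney_u,
    normality_screen,
    t_test_power,
    tost_equivalence,
)


def exact_mwu_p(x, y, alternative):
    """Independent oracle: enumerate every label assignment of the pooled sample."""
    pooled = list(x) + list(y)
    nx = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
        1 for xi in x for yi in y if xi == yi
    )
    us = []
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(1 for xi in xs for yi in ys if xi > yi))
    us = np.array(us, dtype=float)
    if alternative == "greater":
        return float(np.mean(us >= u_obs))
    if alternative == "less":
        return float(np.mean(us <= u_obs))
    lo = min(np.mean(us >= u_obs), np.mean(us <= u_obs))
    return float(min(1.0, 2 * lo))


class TestCohensD:
    def test_interference_time_summaries(self):
        d = cohens_d(GroupSummary(144, 43.61, 28.04), GroupSummary(146, 33.50, 15.99))
        assert d == pytest.approx(0.44, abs=0.005)

    def test_perceptual_strength_summaries(self):
        a, b = GroupSummary(144, 0.48, 0.19), GroupSummary(146, 0.52, 0.16)
        assert cohens_d(a, b) == pytest.approx(-0.23, abs=0.005)
        assert a.mean - b.mean == pytest.approx(-0.04, abs=1e-12)

    def test_boundary_summaries(self):
        d = cohens_d(GroupSummary(144, 0.082, 0.044), GroupSummary(146, 0.066, 0.036))
        assert d == pytest.approx(0.40, abs=0.005)

    def test_equal_means_give_zero(self):
        assert cohens_d(GroupSummary(10, 5.0, 1.0), GroupSummary(12, 5.0, 2.0)) == 0.0

    def test_antisymmetric_under_group_swap(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(0.4, 1.2, 40)
        assert cohens_d_from_samples(x, y) == pytest.approx(-cohens_d_from_samples(y, x))

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            cohens_d(GroupSummary(5, 1.0, 0.0), GroupSummary(5, 2.0, 0.0))


class TestBootstrap:
    def test_identical_samples_straddle_zero(self, rng):
        x = rng.normal(0, 1, 60)
        est, (lo, hi) = bootstrap_mean_difference(x, x.copy(), 1000, rng=rng)
        assert est == 0.0
        assert lo < 0 < hi

    def test_location_equivariance(self, rng):
        x = rng.normal(0, 1, 80)
        est, (lo, hi) = bootstrap_mean_difference(x, x + 5.0, 1000, rng=rng)
        assert est == pytest.approx(-5.0, abs=1e-12)
        assert lo <= est <= hi

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(8)
        widths = {}
        for n in (50, 200):
            x, y = rng.normal(0, 1, n), rng.normal(0, 1, n)
            _, (lo, hi) = bootstrap_mean_difference(x, y, 1500, rng=rng)
            widths[n] = hi - lo
        # ~1/sqrt(n): quadrupling n should roughly halve the width
        assert widths[200] < 0.75 * widths[50]

    def test_resample_floor(self, rng):
        with pytest.raises(ValueError):
            bootstrap_mean_difference([1, 2], [3, 4], 10, rng=rng)


class TestTost:
    def test_effect_exactly_on_upper_bound_gives_half_p(self, rng):
        x = rng.normal(0.3, 1.0, 150)
        y = rng.normal(0.0, 1.0, 150)
        d_obs = cohens_d_from_samples(x, y)
        res = tost_equivalence(x, y, d_bounds=(-abs(d_obs), abs(d_obs)))
        assert res.t_upper == pytest.approx(0.0, abs=1e-10)
        assert res.p_upper == pytest.approx(0.5, abs=1e-10)

    def test_identical_large_samples_conclude_equivalence(self, rng):
        x = rng.normal(0, 1, 400)
        y = rng.normal(0, 1, 400)
        res = tost_equivalence(x, y)
        assert res.p_lower < 0.05 and res.p_upper < 0.05
        assert res.equivalent

    def test_infinite_bounds_always_equivalent(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(3, 1, 20)
        assert tost_equivalence(x, y, d_bounds=(-50.0, 50.0)).equivalent

    def test_zero_width_bounds_never_equivalent(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        assert not tost_equivalence(x, y, d_bounds=(0.0, 0.0)).equivalent

    def test_agrees_with_statsmodels_welch_tost(self, rng):
        from statsmodels.stats.weightstats import ttost_ind

        x = rng.normal(0.1, 1.0, 90)
        y = rng.normal(0.0, 1.2, 110)
        res = tost_equivalence(x, y, d_bounds=(-0.31, 0.31))
        lo, hi = res.bounds_raw
        p_sm, lower, upper = ttost_ind(x, y, lo, hi, usevar="unequal")
        assert res.p_lower == pytest.approx(lower[1], abs=1e-10)
        assert res.p_upper == pytest.approx(upper[1], abs=1e-10)
        assert res.p_tost == pytest.approx(p_sm, abs=1e-10)


class TestMannWhitney:
    def test_hand_enumerated_example(self):
        u, p = mann_whitney_u([3, 4, 5], [1, 2], alternative="greater")
        assert u == 6.0
        assert p == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    def test_matches_full_enumeration_small_samples(self, alternative):
        rng = np.random.default_rng(12)
        for _ in range(4):
            x = rng.permutation(np.arange(1, 14))[:6].astype(float)
            y = rng.permutation(np.arange(14, 30))[:5].astype(float)
            _, p = mann_whitney_u(x, y, alternative=alternative)
            assert p == pytest.approx(exact_mwu_p(x, y, alternative), abs=1e-9)

    def test_null_expectation(self, rng):
        x, y = rng.normal(0, 1, 200), rng.normal(0, 1, 200)
        u, _ = mann_whitney_u(x, y)
        assert abs(u - 200 * 200 / 2) < 4 * np.sqrt(200 * 200 * 401 / 12)

    def test_swap_symmetry(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(1, 1, 12)
        u_xy, _ = mann_whitney_u(x, y)
        u_yx, _ = mann_whitney_u(y, x)
        assert u_xy + u_yx == pytest.approx(15 * 12)

    def test_exact_and_asymptotic_agree_on_tiefree_samples(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        _, p_exact = mann_whitney_u(x, y)  # 225 <= 400 -> exact
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert abs(p_exact - res.pvalue) < 0.01

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 1500
        for _ in range(n_rep):
            x, y = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
            _, p = mann_whitney_u(x, y, alternative="greater")
            rejections += p < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_empty_sample_invalid(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPower:
    def test_planning_value(self):
        assert t_test_power(130, 0.31, alpha=0.05, sides=1) == pytest.approx(0.80, abs=0.005)

    def test_null_effect_gives_alpha(self):
        assert t_test_power(50, 0.0, alpha=0.05, sides=1) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_n_and_effect(self):
        assert t_test_power(200, 0.31) > t_test_power(130, 0.31)
        assert t_test_power(130, 0.5) > t_test_power(130, 0.31)
        assert t_test_power(130, -0.5, sides=2) == pytest.approx(
            t_test_power(130, 0.5, sides=2), abs=1e-12
        )


class TestNormalityScreen:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(21)
        ps = [normality_screen(rng.normal(0, 1, 150))[1] for _ in range(40)]
        assert np.mean(np.array(ps) < 0.05) < 0.25  # calibrated at coarse tolerance

    def test_skewed_sample_flagged(self):
        rng = np.random.default_rng(22)
        flags = [normality_screen(rng.exponential(1.0, 100))[1] < 0.05 for _ in range(20)]
        assert np.mean(flags) > 0.9

    def test_constant_sample_degenerate(self):
        with pytest.raises(ValueError):
            normality_screen(np.ones(10))

    def test_size_limits(self):
        with pytest.raises(ValueError):
            normality_screen([1.0, 2.0])
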