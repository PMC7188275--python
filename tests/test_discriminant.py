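import numpy as np
import pytest
from scipy.integrate import quad

from tfopt.discriminant import (
    DistanceSet,
    SeparabilityError,
    discrete_error_rates,
    distance_set,
    distances,
    gaussian_tail_above,
    gradient,
    is_unimodal,
    select_sigma,
    slice_optimal_threshold,
    smoothed_distributions,
    total_error,
)
from tfopt.template import SliceSets


class TestDistances:
    def test_slice_equal_to_template_has_zero_distance(self):
        v = np.linspace(0, 1, 129)
        assert distances(v, v[None, :])[0] == 0.0

    def test_all_ones_vs_all_zeros_is_sqrt_dim(self):
        d = distances(np.zeros(129), np.ones((1, 129)))[0]
        assert d == pytest.approx(np.sqrt(129))

    def test_matches_brute_force_sum_of_squares(self, rng):
        t = rng.standard_normal(129)
        s = rng.standard_normal((40, 129))
        expected = np.sqrt(((s - t) ** 2).sum(axis=1))
        np.testing.assert_allclose(distances(t, s), expected, rtol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distances(np.zeros(10), np.zeros((2, 9)))


class TestGaussianTail:
    def test_at_threshold_is_half(self):
        assert gaussian_tail_above(1.3, 1.3, 0.2) == pytest.approx(0.5)

    def test_far_tail_saturates(self):
        assert gaussian_tail_above(1.0 + 10 * 0.1, 1.0, 0.1) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_matches_numeric_quadrature(self, rng):
        for _ in range(100):
            d = rng.uniform(0, 3)
            theta = rng.uniform(0, 3)
            sigma = rng.uniform(0.05, 1.0)

            def pdf(x):
                return np.exp(-0.5 * ((x - d) / sigma) ** 2) / (
                    sigma * np.sqrt(2 * np.pi)
                )

            expected, _ = quad(pdf, theta, d + 12 * sigma)
            assert gaussian_tail_above(d, theta, sigma) == pytest.approx(
                expected, abs=1e-8
            )

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_tail_above(1.0, 1.0, 0.0)


class TestTotalError:
    def test_perfect_separation_is_zero(self):
        ds = DistanceSet(np.zeros(5), np.full(7, 10.0))
        assert total_error(ds, 5.0, 0.2) < 1e-12

    def test_identical_point_masses_give_half(self):
        ds = DistanceSet(np.full(4, 2.0), np.full(6, 2.0))
        assert total_error(ds, 2.0, 0.3) == pytest.approx(0.5)

    def test_matches_monte_carlo_oracle(self, rng):
        ds = DistanceSet(rng.uniform(0, 1, 8), rng.uniform(0.5, 2.5, 12))
        theta, sigma = 0.9, 0.3
        te = total_error(ds, theta, sigma)
        n = 1_000_000
        draws_t = ds.target_distances[:, None] + sigma * rng.standard_normal(
            (ds.M, n // 100)
        )
        draws_d = ds.distractor_distances[
            :, None
        ] + sigma * rng.standard_normal((ds.N, n // 100))
        fn = (draws_t > theta).mean()
        fp = (draws_d <= theta).mean()
        mc = (fn + fp) / 2
        se = 0.5 / np.sqrt(min(draws_t.size, draws_d.size))
        assert te == pytest.approx(mc, abs=3 * se)

    def test_saturates_to_half_as_sigma_grows(self, rng):
        ds = DistanceSet(rng.uniform(0, 1, 5), rng.uniform(2, 3, 9))
        assert total_error(ds, 1.5, 1e4) == pytest.approx(0.5, abs=1e-3)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            ds = DistanceSet(rng.uniform(0, 3, 6), rng.uniform(0, 3, 11))
            te = total_error(ds, rng.uniform(0, 3), rng.uniform(0.05, 2))
            assert 0.0 <= te <= 1.0


class TestUnimodality:
    def test_monotone_and_single_peak_pass(self):
        assert is_unimodal(np.array([0, 1, 2, 3.0]))
        assert is_unimodal(np.array([0, 2, 3, 1, 0.5]))

    def test_two_peaks_fail(self):
        assert not is_unimodal(np.array([0, 2, 1, 2, 0.0]))

    def test_valley_first_fails(self):
        assert not is_unimodal(np.array([2, 1, 2.0]))


class TestSelectSigma:
    def test_tight_cluster_reaches_search_floor(self):
        ds = DistanceSet(
            np.array([1.0, 1.001, 0.999]), np.array([3.0, 3.001, 2.999])
        )
        assert select_sigma(ds) == pytest.approx(0.05)

    def test_strict_mode_never_goes_below_default(self):
        ds = DistanceSet(
            np.array([1.0, 1.001]), np.array([3.0, 3.001])
        )
        assert select_sigma(ds, strict_floor_at_init=True) == pytest.approx(0.2)

    def test_bimodal_distractors_force_larger_sigma(self):
        ds = DistanceSet(np.array([1.0, 1.0, 1.0]), np.array([1.0, 3.0]))
        sigma = select_sigma(ds)
        assert sigma > 0.2
        sd = smoothed_distributions(ds, sigma)
        assert is_unimodal(sd.T) and is_unimodal(sd.D)

    def test_returned_sigma_is_minimal_on_grid(self):
        ds = DistanceSet(
            np.array([0.5, 0.6, 0.7]), np.array([1.0, 1.8, 2.6])
        )
        sigma = select_sigma(ds)
        sd = smoothed_distributions(ds, sigma)
        assert is_unimodal(sd.T) and is_unimodal(sd.D)
        if sigma > 0.05 + 1e-9:
            below = smoothed_distributions(ds, sigma - 0.05)
            assert not (is_unimodal(below.T) and is_unimodal(below.D))


class TestSliceOptimalThreshold:
    def test_symmetric_equal_counts_cross_at_midpoint(self):
        ds = DistanceSet(np.array([0.0]), np.array([2.0]))
        theta = slice_optimal_threshold(ds, 0.2)
        assert theta == pytest.approx(1.0, abs=1e-6)

    def test_crossing_matches_independent_root_of_density_equation(self):
        # T(x) = G(x), D(x) = (G(x-1.7) + G(x-2.3))/2; solve T = D with an
        # independently written formula and a stock root finder
        from scipy.optimize import brentq as brentq_oracle

        sigma = 0.4
        ds = DistanceSet(np.array([0.0]), np.array([1.7, 2.3]))
        theta = slice_optimal_threshold(ds, sigma)

        def g(x, mu):
            return np.exp(-0.5 * ((x - mu) / sigma) ** 2)

        expected = brentq_oracle(
            lambda x: g(x, 0.0) - 0.5 * (g(x, 1.7) + g(x, 2.3)), 0.0, 1.7
        )
        assert theta == pytest.approx(expected, abs=1e-6)

    def test_matches_dense_grid_argmin_oracle(self, rng):
        ds = DistanceSet(
            rng.uniform(0.2, 0.6, 30), rng.uniform(1.2, 2.5, 60)
        )
        sigma = select_sigma(ds)
        theta = slice_optimal_threshold(ds, sigma)
        sd = smoothed_distributions(ds, sigma)
        i_t = int(np.argmax(sd.T))
        diff = sd.T[i_t:] - sd.D[i_t:]
        k = int(np.flatnonzero(np.sign(diff[:-1]) * np.sign(diff[1:]) < 0)[0])
        grid_theta = sd.grid[i_t + k]
        spacing = sd.grid[1] - sd.grid[0]
        assert abs(theta - grid_theta) <= 2 * spacing

    def test_inseparable_peaks_raise(self):
        ds = DistanceSet(np.array([2.0, 2.1]), np.array([0.5, 0.6]))
        with pytest.raises(SeparabilityError):
            slice_optimal_threshold(ds, select_sigma(ds))


class TestGradient:
    def make_sets(self, rng, m=6, n=9, bins=10):
        return SliceSets(
            targets=rng.uniform(0, 1, (m, bins)),
            distractors=rng.uniform(0, 1, (n, bins)),
        )

    def test_slice_at_template_contributes_zero(self, rng):
        # all targets coincide with the template (distance 0): the target
        # half of the gradient drops out entirely, leaving the distractor
        # push computed here independently
        t = rng.uniform(0, 1, 10)
        sets = SliceSets(
            targets=np.tile(t, (3, 1)),
            distractors=rng.uniform(0, 1, (5, 10)),
        )
        theta, sigma = 0.5, 0.2
        g = gradient(t, sets, theta, sigma)
        d = np.sqrt(((sets.distractors - t) ** 2).sum(axis=1))
        w = np.exp(-0.5 * ((theta - d) / sigma) ** 2) / (
            sigma * np.sqrt(2 * np.pi)
        )
        expected = -(w[:, None] * (sets.distractors - t) / d[:, None]).sum(
            axis=0
        ) / (2 * sets.N)
        np.testing.assert_allclose(g, expected, rtol=1e-12)

    def test_far_from_threshold_gradient_vanishes(self, rng):
        sets = SliceSets(
            targets=np.zeros((3, 5)), distractors=np.ones((3, 5)) * 100
        )
        t = np.zeros(5) + 0.001
        g = gradient(t, sets, 50.0, 0.2)  # everything > 10 sigma from theta
        np.testing.assert_allclose(g, 0.0, atol=1e-30)

    def test_matches_central_finite_differences(self, rng):
        sets = self.make_sets(rng, m=8, n=12, bins=10)
        t = rng.uniform(0.2, 0.8, 10)
        theta, sigma = 0.8, 0.25
        g = gradient(t, sets, theta, sigma)
        eps = 1e-6
        fd = np.zeros_like(t)
        for i in range(t.size):
            tp, tm = t.copy(), t.copy()
            tp[i] += eps
            tm[i] -= eps
            fd[i] = (
                total_error(distance_set(tp, sets), theta, sigma)
                - total_error(distance_set(tm, sets), theta, sigma)
            ) / (2 * eps)
        np.testing.assert_allclose(g, -fd, rtol=1e-4, atol=1e-10)


class TestDiscreteErrors:
    def test_perfect_separation(self):
        ds = DistanceSet(np.array([0.1, 0.2]), np.array([2.0, 3.0]))
        assert discrete_error_rates(ds, 1.0) == (0.0, 0.0, 0.0)

    def test_theta_below_everything_misses_all_targets(self):
        ds = DistanceSet(np.array([1.0, 2.0]), np.array([3.0]))
        fn, fp, err = discrete_error_rates(ds, 0.5)
        assert (fn, fp, err) == (1.0, 0.0, 50.0)

    def test_matches_brute_force_count_oracle(self, rng):
        ds = DistanceSet(rng.uniform(0, 2, 50), rng.uniform(0, 2, 70))
        theta = 1.0
        fn, fp, err = discrete_error_rates(ds, theta)
        fn_oracle = sum(d > theta for d in ds.target_distances) / 50
        fp_oracle = sum(d <= theta for d in ds.distractor_distances) / 70
        assert fn == fn_oracle and fp == fp_oracle
        assert err == pytest.approx(100 * (fn_oracle + fp_oracle) / 2)

    def test_match_rule_is_inclusive_at_theta(self):
        ds = DistanceSet(np.array([1.0]), np.array([1.0]))
        fn, fp, _ = discrete_error_rates(ds, 1.0)
        assert fn == 0.0 and fp == 1.0
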