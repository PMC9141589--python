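"""Fractional Brownian motion sampling and multi-point bridge conditioning."""

import numpy as np
import pytest

from phaspasto import (
    FbmNumericalError,
    TimeSeries,
    condition_on_points,
    fbm_covariance,
    fbm_covariance_matrix,
    interpolate_gaps,
    sample_fbm,
)
from phaspasto.fbm import bridge_interpolate


class TestCovariance:
    @pytest.mark.parametrize(
        "t, tp, h, expected",
        [
            (1.0, 1.0, 0.3, 1.0),
            (2.0, 3.0, 0.5, 2.0),  # Brownian case collapses to min(t, t')
            (1.0, 2.0, 0.75, np.sqrt(2.0)),
        ],
    )
    def test_values(self, t, tp, h, expected):
        assert fbm_covariance(t, tp, h) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, rng):
        t = rng.uniform(0, 10, 50)
        tp = rng.uniform(0, 10, 50)
        for h in (0.2, 0.5, 0.8):
            np.testing.assert_allclose(
                fbm_covariance(t, tp, h), fbm_covariance(tp, t, h), rtol=0, atol=0
            )

    @pytest.mark.parametrize("h", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_invalid_hurst(self, h):
        with pytest.raises(ValueError, match="Hurst"):
            fbm_covariance(1.0, 2.0, h)

    def test_rejects_negative_times(self):
        with pytest.raises(ValueError, match="non-negative"):
            fbm_covariance(-1.0, 2.0, 0.5)


class TestSampling:
    def test_pinned_at_origin(self):
        assert sample_fbm([0.0], 0.3, seed=0) == pytest.approx([0.0])
        path = sample_fbm(np.arange(0.0, 5.0), 0.7, seed=1)
        assert path[0] == 0.0

    def test_seeded_determinism(self):
        grid = np.linspace(0, 10, 40)
        a = sample_fbm(grid, 0.6, seed=42)
        b = sample_fbm(grid, 0.6, seed=42)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, sample_fbm(grid, 0.6, seed=43))

    @pytest.mark.parametrize("h, checks", [(0.5, (50, 100, 200)), (0.8, (100,))])
    def test_marginal_variance_matches_closed_form(self, h, checks):
        """Monte-Carlo Var[X(t)] against the fBm law t^{2H}."""
        grid = np.arange(0.0, 201.0)
        paths = np.array([sample_fbm(grid, h, seed=s) for s in range(2000)])
        for t in checks:
            empirical = paths[:, t].var()
            assert empirical == pytest.approx(float(t) ** (2 * h), rel=0.10)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            sample_fbm([0.0, 2.0, 1.0], 0.5, seed=0)
        with pytest.raises(ValueError):
            sample_fbm([-1.0, 1.0], 0.5, seed=0)


class TestConditioning:
    def test_single_constraint_hits_value(self, rng):
        grid = np.linspace(0, 2, 21)
        path = sample_fbm(grid, 0.4, seed=7)
        bridged = condition_on_points(grid, path, 0.4, [1.0], [5.0])
        assert bridged[10] == pytest.approx(5.0, abs=1e-10)

    def test_zero_path_brownian_bridge_mean_is_linear(self):
        """Kriging mean for H=1/2 with one endpoint constraint is 5t."""
        grid = np.linspace(0, 1, 101)
        bridged = condition_on_points(grid, np.zeros(101), 0.5, [1.0], [5.0])
        np.testing.assert_allclose(bridged, 5.0 * grid, atol=1e-8)

    def test_zero_path_piecewise_linear_for_consecutive_constraints(self):
        grid = np.arange(0.0, 11.0)
        ct = np.array([3.0, 7.0, 10.0])
        cx = np.array([1.5, -2.0, 4.0])
        bridged = condition_on_points(grid, np.zeros(11), 0.5, ct, cx)
        expected = np.interp(grid, np.concatenate([[0.0], ct]), np.concatenate([[0.0], cx]))
        np.testing.assert_allclose(bridged, expected, atol=1e-8)

    @pytest.mark.parametrize("h", np.round(np.arange(0.1, 1.0, 0.1), 1).tolist())
    def test_constraint_exactness(self, h, rng):
        """Bridge reproduces every prescribed point to better than 1e-8."""
        grid = np.unique(rng.uniform(0.1, 50.0, 300))
        path = sample_fbm(grid, h, rng)
        n_con = int(rng.integers(1, 31))
        idx = rng.choice(grid.size, size=n_con, replace=False)
        cx = rng.normal(0, 3, n_con)
        bridged = condition_on_points(grid, path, h, grid[idx], cx)
        order = np.argsort(grid[idx])
        assert np.max(np.abs(bridged[np.sort(idx)] - cx[order])) < 1e-8

    def test_idempotence(self, rng):
        """Conditioning a path already satisfying the constraints is the identity."""
        grid = np.linspace(0, 5, 51)
        path = sample_fbm(grid, 0.65, rng)
        ct, cx = grid[[10, 30, 45]], path[[10, 30, 45]]
        once = condition_on_points(grid, path, 0.65, ct, cx)
        np.testing.assert_allclose(once, path, atol=1e-9)
        twice = condition_on_points(grid, once, 0.65, ct, once[[10, 30, 45]])
        np.testing.assert_allclose(twice, once, atol=1e-9)

    def test_conditional_law_matches_direct_gaussian_algebra(self):
        """Bridge law on a 3-point grid against brute-force 3x3 conditioning."""
        grid = np.array([1.0, 2.0, 3.0])
        h = 0.7
        cov = fbm_covariance_matrix(grid, h)
        # condition X(2) = 1.2 by explicit partitioned-Gaussian formulas
        free = [0, 2]
        s12 = cov[np.ix_(free, [1])]
        mean_exact = (s12 / cov[1, 1]).ravel() * 1.2
        cov_exact = cov[np.ix_(free, free)] - (s12 @ s12.T) / cov[1, 1]

        rng = np.random.default_rng(99)
        samples = np.array(
            [
                condition_on_points(grid, sample_fbm(grid, h, rng), h, [2.0], [1.2])
                for _ in range(10_000)
            ]
        )
        np.testing.assert_allclose(samples[:, 1], 1.2, atol=1e-10)
        emp_mean = samples[:, free].mean(axis=0)
        emp_var = samples[:, free].var(axis=0)
        se_mean = np.sqrt(np.diag(cov_exact) / 10_000)
        se_var = np.diag(cov_exact) * np.sqrt(2.0 / 10_000)
        assert np.all(np.abs(emp_mean - mean_exact) < 5 * se_mean)
        assert np.all(np.abs(emp_var - np.diag(cov_exact)) < 5 * se_var)

    def test_duplicate_and_origin_constraints_rejected(self):
        grid = np.linspace(0, 1, 11)
        path = np.zeros(11)
        with pytest.raises(ValueError, match="duplicate.*0.5"):
            condition_on_points(grid, path, 0.5, [0.5, 0.5], [1.0, 2.0])
        with pytest.raises(ValueError, match="pinned"):
            condition_on_points(grid, path, 0.5, [0.0], [1.0])

    def test_constraint_must_be_grid_member(self):
        grid = np.linspace(0, 1, 11)
        with pytest.raises(ValueError, match="not a grid point"):
            condition_on_points(grid, np.zeros(11), 0.5, [0.55], [1.0])


class TestInterpolateGaps:
    def test_requires_at_least_one_point_per_gap(self, short_series):
        with pytest.raises(ValueError, match="points_per_gap"):
            interpolate_gaps(short_series, 0, 0.5, seed=0)

    def test_requires_two_observed_points(self):
        one = TimeSeries([0.0], [1.0])
        with pytest.raises(ValueError, match="at least 2"):
            interpolate_gaps(one, 3, 0.5, seed=0)

    def test_observed_points_unchanged_and_uniform_placement(self, short_series):
        out = interpolate_gaps(short_series, 3, 0.35, seed=5)
        assert len(out) == 4 * (len(short_series) - 1) + 1
        np.testing.assert_array_equal(out.x[::4], short_series.x)
        np.testing.assert_allclose(out.t[:5], np.linspace(0.0, 1.0, 5), atol=1e-12)
        np.testing.assert_allclose(out.t[4:9], np.linspace(1.0, 2.5, 5), atol=1e-12)

    def test_fixed_seed_reproducible(self, short_series):
        a = interpolate_gaps(short_series, 2, 0.5, seed=123)
        b = interpolate_gaps(short_series, 2, 0.5, seed=123)
        assert a.equals(b)

    def test_interior_mean_is_brownian_bridge_line(self):
        """For H=1/2 the conditional mean joins the two observations linearly."""
        obs = TimeSeries([0.0, 1.0], [3.0, 7.0])
        acc = np.zeros(5)
        n = 5000
        for s in range(n):
            acc += interpolate_gaps(obs, 3, 0.5, seed=s).x
        mean = acc / n
        # conditional sd at mid-gap is sqrt(1) in index units; SE ~ 1/sqrt(n)
        np.testing.assert_allclose(mean, np.linspace(3.0, 7.0, 5), atol=5 * 1.0 / np.sqrt(n))

    def test_per_gap_counts(self, short_series):
        out = bridge_interpolate(short_series, [2, 0, 1, 3], 0.5, seed=2)
        assert len(out) == len(short_series) + 6
        anchors = np.concatenate([[0], np.cumsum(np.array([2, 0, 1, 3]) + 1)])
        np.testing.assert_array_equal(out.x[anchors], short_series.x)

    def test_failed_factorization_is_reported(self):
        """An indefinite matrix must raise, not be silently regularized."""
        from phaspasto.fbm import _cholesky_with_jitter

        indefinite = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(FbmNumericalError, match="not positive definite"):
            _cholesky_with_jitter(indefinite)
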