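"""Smoothing, curvature, hulls and the logistic severity fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemoshock import trajectory as tj

REFERENCE_PARAMS = (-19.0, -0.36, 9.38, 24.5)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        x = np.full(50, 3.7)
        assert np.allclose(tj.smooth_series(x, 7), x)

    def test_window_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=30)
        assert np.array_equal(tj.smooth_series(x, 1), x)

    def test_hand_convolution_interior(self):
        out = tj.smooth_series(np.array([1.0, 2, 3, 4, 5]), 3)
        assert np.allclose(out[1:4], [2.0, 3.0, 4.0])

    def test_even_or_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            tj.smooth_series(np.arange(10.0), 4)
        with pytest.raises(ValueError):
            tj.smooth_series(np.arange(10.0), 11)

    @given(st.lists(st.floats(-10, 10), min_size=9, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_interior_mean_preserved(self, data):
        """The shrunken-window moving average preserves interior window sums."""
        x = np.asarray(data)
        out = tj.smooth_series(x, 3)
        for i in range(1, len(x) - 1):
            assert out[i] == pytest.approx(np.mean(x[i - 1:i + 2]), abs=1e-9)


class TestCurvature:
    def test_circle_curvature_is_inverse_radius(self):
        t = np.linspace(0, 2 * np.pi, 1000)
        traj = tj.Trajectory(2 * np.cos(t), 2 * np.sin(t))
        k = tj.curvature(traj)
        assert np.allclose(k[5:-5], 0.5, rtol=0.01)

    def test_straight_line_has_zero_curvature(self):
        x = np.linspace(0, 10, 200)
        k = tj.curvature(tj.Trajectory(x, 3 * x + 1))
        assert np.max(k) < 1e-10

    def test_parabola_vertex_curvature(self):
        x = np.linspace(-1, 1, 1001)
        k = tj.curvature(tj.Trajectory(x, x ** 2))
        assert k[500] == pytest.approx(2.0, rel=0.01)

    def test_translation_and_rotation_invariance(self):
        t = np.linspace(0, np.pi, 500)
        x, y = np.cos(t), np.sin(t) + 0.3 * t
        k0 = tj.curvature(tj.Trajectory(x, y))
        th = 0.7
        xr = math.cos(th) * x - math.sin(th) * y + 5.0
        yr = math.sin(th) * x + math.cos(th) * y - 2.0
        k1 = tj.curvature(tj.Trajectory(xr, yr))
        assert np.allclose(k0[3:-3], k1[3:-3], rtol=1e-8)

    def test_uniform_scaling_scales_curvature_inversely(self):
        t = np.linspace(0, 2 * np.pi, 800)
        traj = tj.Trajectory(np.cos(t), np.sin(t))
        scaled = tj.Trajectory(3 * traj.x, 3 * traj.y)
        k0 = tj.curvature(traj)
        k1 = tj.curvature(scaled)
        assert np.allclose(k1[5:-5], k0[5:-5] / 3.0, rtol=1e-8)

    def test_degenerate_point_warns_and_zeroes(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 2.0, 3.0, 4.0])
        with pytest.warns(RuntimeWarning):
            k = tj.curvature(tj.Trajectory(x, x))
        assert np.all(np.isfinite(k))


class TestMaxCurvaturePoint:
    def test_arc_between_straight_lines_found_on_arc(self):
        """Line → quarter-circle (radius r) → line: max curvature ≈ 1/r on the arc."""
        r = 2.0
        seg1 = np.stack([np.linspace(-5, 0, 300), np.zeros(300)], axis=1)
        th = np.linspace(-np.pi / 2, 0.0, 200)
        arc = np.stack([r * np.cos(th), r + r * np.sin(th)], axis=1)
        seg2 = np.stack([np.full(300, r), np.linspace(r, 6, 300)], axis=1)
        pts = np.vstack([seg1, arc[1:], seg2[1:]])
        traj = tj.Trajectory(pts[:, 0], pts[:, 1])
        cp = tj.max_curvature_point(traj, window=9)
        assert cp.k == pytest.approx(1.0 / r, rel=0.15)
        assert 300 - 9 <= cp.index <= 300 + 200 + 9

    def test_ellipse_max_curvature_at_major_axis_ends(self):
        a, b = 2.0, 1.0
        t = np.linspace(0, 2 * np.pi, 2001)
        traj = tj.Trajectory(a * np.cos(t), b * np.sin(t))
        cp = tj.max_curvature_point(traj, window=5)
        assert cp.k == pytest.approx(a / b ** 2, rel=0.02)
        assert abs(abs(cp.x) - a) < 0.05

    def test_tie_breaks_to_earliest_of_exact_duplicates(self):
        """Two bitwise-identical laps of a circle: the max lands in lap one."""
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        x = np.tile(np.cos(t), 2)
        y = np.tile(np.sin(t), 2)
        cp = tj.max_curvature_point(tj.Trajectory(x, y), window=5)
        assert cp.k == pytest.approx(1.0, rel=0.01)
        assert cp.index < len(t) + 5

    def test_zero_curvature_everywhere_raises(self):
        x = np.linspace(0, 1, 100)
        with pytest.raises(ValueError, match="turning point"):
            tj.max_curvature_point(tj.Trajectory(x, 2 * x), window=5)


class TestHullRegion:
    def test_unit_square(self):
        h = tj.hull_region(np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]]))
        assert h.area == pytest.approx(1.0)
        assert len(h.vertices) == 4

    def test_triangle_area(self):
        h = tj.hull_region(np.array([[0, 0], [1, 0], [0, 1.0]]))
        assert h.area == pytest.approx(0.5)

    def test_interior_points_do_not_change_hull(self):
        rng = np.random.default_rng(3)
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        interior = rng.uniform(0.05, 0.95, size=(20, 2))
        h1 = tj.hull_region(corners)
        h2 = tj.hull_region(np.vstack([corners, interior]))
        assert h2.area == pytest.approx(h1.area)
        assert sorted(map(tuple, h2.vertices)) == sorted(map(tuple, h1.vertices))

    def test_hull_contains_all_inputs_and_ignores_order(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(30, 2))
        h1 = tj.hull_region(pts)
        h2 = tj.hull_region(pts[::-1])
        assert h2.area == pytest.approx(h1.area)
        for p in pts:
            assert h1.contains(tuple(p))

    def test_collinear_points_raise_degenerate_error(self):
        x = np.linspace(0, 1, 5)
        with pytest.raises(tj.DegenerateHullError):
            tj.hull_region(np.stack([x, 2 * x], axis=1))


class TestLogisticFit:
    def test_noiseless_parameter_recovery(self):
        x = np.linspace(0, 20, 60)
        y = tj.logistic4(x, *REFERENCE_PARAMS)
        res = tj.fit_logistic(x, y)
        for got, want in zip(res.params, REFERENCE_PARAMS):
            assert got == pytest.approx(want, rel=1e-4)

    def test_midpoint_value(self):
        x = np.linspace(0, 20, 60)
        res = tj.fit_logistic(x, tj.logistic4(x, *REFERENCE_PARAMS))
        a, b, c, d = res.params
        assert res.predict(c) == pytest.approx(a / 2 + d)
        assert res.predict(9.38) == pytest.approx(15.0, abs=1e-3)

    def test_asymptotes(self):
        x = np.linspace(0, 20, 60)
        res = tj.fit_logistic(x, tj.logistic4(x, *REFERENCE_PARAMS))
        low_bv, high_bv = res.asymptotes
        assert low_bv == pytest.approx(24.5, abs=1e-3)
        assert high_bv == pytest.approx(5.5, abs=1e-3)

    def test_model_results_summary_mentions_parameters(self):
        x = np.linspace(0, 20, 60)
        rng = np.random.default_rng(0)
        model = tj.LogisticSeverityModel(x, tj.logistic4(x, *REFERENCE_PARAMS)
                                         + rng.normal(0, 0.5, x.size))
        res = model.fit()
        text = res.summary()
        for name in ("a", "b", "c", "d", "residual sd"):
            assert name in text

    def test_recovery_under_noise_property(self):
        """Median |error| of each parameter < 10% over repeated noisy fits."""
        rng = np.random.default_rng(42)
        x = np.linspace(0, 20, 100)
        errs = []
        for _ in range(100):
            y = tj.logistic4(x, *REFERENCE_PARAMS) + rng.normal(0, 1.0, x.size)
            res = tj.fit_logistic(x, y)
            errs.append(np.abs((res.params - np.array(REFERENCE_PARAMS))
                               / np.array(REFERENCE_PARAMS)))
        med = np.median(np.array(errs), axis=0)
        assert np.all(med < 0.10)


class TestPredictionInterval:
    def _fit(self, sd=1.0, n=100, seed=5):
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 20, n)
        y = tj.logistic4(x, *REFERENCE_PARAMS) + rng.normal(0, sd, n)
        return tj.fit_logistic(x, y)

    def test_zero_covariance_half_width_is_z_times_sd(self):
        res = self._fit()
        res.covariance = np.zeros((4, 4))
        lo, hi = res.prediction_interval(10.0, level=0.95)
        half = (hi - lo) / 2.0
        assert half == pytest.approx(1.959964 * res.residual_sd, rel=1e-6)

    def test_interval_widens_with_parameter_uncertainty(self):
        res = self._fit()
        lo1, hi1 = res.prediction_interval(10.0)
        res.covariance = res.covariance * 25.0
        lo2, hi2 = res.prediction_interval(10.0)
        assert (hi2 - lo2) > (hi1 - lo1)

    def test_invalid_level_rejected(self):
        res = self._fit()
        with pytest.raises(ValueError):
            res.prediction_interval(10.0, level=1.5)

    def test_empirical_coverage_near_nominal(self):
        """Fresh draws fall inside the 95% interval 90–99% of the time."""
        rng = np.random.default_rng(17)
        x = np.linspace(0, 20, 100)
        res = self._fit(seed=23)
        lo, hi = res.prediction_interval(x, level=0.95)
        inside = 0
        trials = 50
        for _ in range(trials):
            y_new = tj.logistic4(x, *REFERENCE_PARAMS) + rng.normal(0, 1.0, x.size)
            inside += np.mean((y_new >= lo) & (y_new <= hi))
        coverage = inside / trials
        assert 0.90 <= coverage <= 0.99


class TestInverse:
    def _res(self):
        x = np.linspace(0, 20, 60)
        return tj.fit_logistic(x, tj.logistic4(x, *REFERENCE_PARAMS))

    def test_midpoint_inverts_to_c(self):
        assert self._res().invert(15.0) == pytest.approx(9.38, abs=1e-3)

    def test_round_trip_identity(self):
        res = self._res()
        for bv in np.linspace(2, 18, 9):
            assert res.invert(float(res.predict(bv))) == pytest.approx(
                bv, abs=1e-8)

    def test_asymptote_is_domain_error(self):
        with pytest.raises(ValueError, match="outside"):
            self._res().invert(24.5)
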