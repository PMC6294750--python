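import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myotract.io import Tract, TractSet
from myotract.quant import (
    CosineCurve,
    SlicePlane,
    canonical_orientation,
    fit_cosine_series,
    heading_and_curvature,
    heading_histogram,
    heading_symmetry,
    slice_tracts,
    tract_mean_heading,
)


def brute_force_crossings(points, plane):
    """Independent oracle: count strict sign changes of the plane distance."""
    d = (points - plane.origin) @ plane.normal
    d = d[np.abs(d) > 0]  # drop exact zeros; test polylines avoid them
    return int(np.sum(d[:-1] * d[1:] < 0))


class TestSlicing:
    def test_perpendicular_line_crosses_once(self):
        t = Tract(points=np.linspace([-5, 0, 0], [5, 0, 0], 11))
        plane = SlicePlane(origin=[0.2, 0, 0], normal=[1, 0, 0])
        recs = slice_tracts(TractSet(tracts=[t]), plane)
        assert len(recs) == 1
        point, direction, idx = recs[0]
        np.testing.assert_allclose(point, [0.2, 0, 0], atol=1e-12)
        np.testing.assert_allclose(np.abs(direction @ plane.normal), 1.0)
        assert idx == 0

    def test_one_sided_tract_never_crosses(self):
        t = Tract(points=np.linspace([1, 0, 0], [5, 3, 0], 9))
        recs = slice_tracts(
            TractSet(tracts=[t]), SlicePlane(origin=[0, 0, 0], normal=[1, 0, 0])
        )
        assert recs == []

    def test_s_shaped_tract_crosses_three_times(self):
        t = np.linspace(0, 1, 200)
        pts = np.stack([np.cos(3 * np.pi * t) + 1e-6, 30 * t, np.zeros_like(t)], axis=1)
        plane = SlicePlane(origin=[0, 0, 0], normal=[1, 0, 0])
        recs = slice_tracts(TractSet(tracts=[Tract(points=pts)]), plane)
        assert len(recs) == brute_force_crossings(pts, plane) == 3

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_crossing_count_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(0, 1.0, (30, 3)), axis=0)
        plane = SlicePlane(origin=rng.normal(0, 1, 3), normal=rng.normal(0, 1, 3))
        recs = slice_tracts(TractSet(tracts=[Tract(points=pts)]), plane)
        assert len(recs) == brute_force_crossings(pts, plane)


def eval_cosine(coeffs, t):
    k = np.arange(len(coeffs))
    return np.cos(np.pi * np.outer(t, k)) @ coeffs


class TestCosineFit:
    def test_exact_recovery_of_order_two_curve(self):
        """A curve synthesized from an order-2 series is reproduced exactly
        when fit at the matching parametrization."""
        coeffs = np.array([[1.0, -2.0, 0.5], [0.3, 1.0, 0.0], [0.0, 0.4, -0.2]])
        t = np.linspace(0, 1, 40)
        pts = eval_cosine(coeffs, t)
        fit = fit_cosine_series(Tract(points=pts), order=2, parameter="uniform")
        np.testing.assert_allclose(fit.coefficients, coeffs, atol=1e-8)
        assert fit.residual_rmse < 1e-10

    def test_constant_coordinate_collapses_to_c0(self):
        t = np.linspace(0, 1, 50)
        pts = np.stack([t * 10, np.full_like(t, 3.25), np.zeros_like(t)], axis=1)
        fit = fit_cosine_series(Tract(points=pts), order=4)
        assert fit.coefficients[0, 1] == pytest.approx(3.25, abs=1e-10)
        np.testing.assert_allclose(fit.coefficients[1:, 1], 0.0, atol=1e-9)

    def test_residual_monotone_in_order(self):
        """Nested least squares: more basis functions never fit worse."""
        t = np.linspace(0, 4 * np.pi, 120)
        pts = np.stack([10 * np.cos(t), 10 * np.sin(t), t], axis=1)  # helix arc
        tract = Tract(points=pts)
        rmse = [fit_cosine_series(tract, K).residual_rmse for K in (1, 3, 5, 9)]
        assert all(a >= b - 1e-12 for a, b in zip(rmse, rmse[1:]))

    def test_translation_moves_only_c0(self):
        rng = np.random.default_rng(5)
        pts = np.cumsum(rng.normal(0, 1, (40, 3)), axis=0)
        f1 = fit_cosine_series(Tract(points=pts), order=5)
        f2 = fit_cosine_series(Tract(points=pts + [10, -3, 7]), order=5)
        assert f2.residual_rmse == pytest.approx(f1.residual_rmse, abs=1e-9)
        np.testing.assert_allclose(
            f2.coefficients[1:], f1.coefficients[1:], atol=1e-9
        )

    def test_resampling_stability(self):
        """Resampling the same polyline at 2x density changes the
        arc-length-parametrized coefficients by < 1e-3 mm."""
        from myotract.cluster import resample_tract

        t = np.linspace(0, 1, 100)
        pts = np.stack([20 * t, 5 * np.sin(np.pi * t), np.zeros_like(t)], axis=1)
        tract = Tract(points=pts)
        dense = Tract(points=resample_tract(tract, 200))
        c1 = fit_cosine_series(tract, order=5).coefficients
        c2 = fit_cosine_series(dense, order=5).coefficients
        assert np.abs(c1 - c2).max() < 1e-3

    def test_too_few_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError):
            fit_cosine_series(Tract(points=pts), order=3)


class TestHeadingCurvature:
    def test_straight_line_angles_and_zero_curvature(self):
        curve = CosineCurve(coefficients=np.array([[0.0, 0, 0], [-10.0, 0, 0]]))
        prof = heading_and_curvature(curve, n_samples=20)
        np.testing.assert_allclose(prof.angles[:, 0], 0.0, atol=1e-9)
        np.testing.assert_allclose(prof.angles[:, 1], 90.0, atol=1e-9)
        np.testing.assert_allclose(prof.curvature, 0.0, atol=1e-12)

    def test_circle_curvature_is_inverse_radius(self):
        """A 10 mm circle has curvature 0.1/mm at every sample."""
        from myotract.quant import curvature_from_derivatives

        theta = np.linspace(0.1, np.pi, 200)
        d1 = np.stack([-10 * np.sin(theta), 10 * np.cos(theta), 0 * theta], axis=1)
        d2 = np.stack([-10 * np.cos(theta), -10 * np.sin(theta), 0 * theta], axis=1)
        kappa = curvature_from_derivatives(d1, d2)
        np.testing.assert_allclose(kappa, 0.1, atol=1e-6)

    def test_mirrored_curve_maps_angle_to_supplement(self):
        coeffs = np.array([[0.0, 0, 0], [-10.0, 2.0, 0], [1.0, 0.5, 0]])
        mirrored = coeffs * np.array([-1, 1, 1])
        p1 = heading_and_curvature(CosineCurve(coefficients=coeffs), 30)
        p2 = heading_and_curvature(CosineCurve(coefficients=mirrored), 30)
        np.testing.assert_allclose(p2.angles[:, 0], 180.0 - p1.angles[:, 0], atol=1e-9)

    def test_analytic_curvature_matches_finite_differences(self):
        """FD curvature on a dense polyline of a smooth curve agrees with
        the analytic profile within 1%."""
        rng = np.random.default_rng(8)
        coeffs = rng.normal(0, 1, (6, 3)) / (np.arange(1, 7)[:, None] ** 2)
        coeffs[1, 0] += 10.0  # dominant smooth sweep
        curve = CosineCurve(coefficients=coeffs)
        t_d = np.linspace(0, 1, 4000)
        pts = curve.evaluate(t_d)
        d1 = np.gradient(pts, t_d, axis=0)
        d2 = np.gradient(d1, t_d, axis=0)
        k_fd = np.linalg.norm(np.cross(d1, d2), axis=1) / np.linalg.norm(d1, axis=1) ** 3
        prof = heading_and_curvature(curve, n_samples=100)
        # away from the stationary endpoints, where |x'| -> 0 makes the
        # quotient numerically meaningless for any estimator
        sel = (prof.t > 0.05) & (prof.t < 0.95)
        fd_at_samples = np.interp(prof.t, t_d, k_fd)[sel]
        err = np.abs(fd_at_samples - prof.curvature[sel]) / np.abs(
            prof.curvature[sel]
        ).max()
        assert err.max() < 0.01

    def test_zero_order_curve_rejected(self):
        with pytest.raises(ValueError):
            heading_and_curvature(CosineCurve(coefficients=np.zeros((1, 3))), 10)


def arc_tract(radius, delta, x1, n=40, flip=False):
    """Purse-style arc through (0, -delta), spanning x in [-x1, x1]."""
    phi1 = np.arcsin(x1 / radius)
    phi = np.linspace(-phi1, phi1, n)
    pts = np.stack(
        [radius * np.sin(phi), (radius - delta) - radius * np.cos(phi),
         np.zeros_like(phi)], axis=1
    )
    if flip:
        pts = -pts
    return Tract(points=pts)


class TestHistograms:
    def test_identical_straight_tracts_fill_one_bin(self):
        t = Tract(points=np.linspace([0, 0, 0], [10, 0, 0], 12))
        counts, edges = heading_histogram(
            TractSet(tracts=[t] * 7), axis="x", bin_width=10.0
        )
        assert counts.sum() == 7
        assert counts[0] == 7  # 0-10 degree bin

    def test_mirrored_population_is_symmetric_about_90(self):
        tracts = [arc_tract(40.0, 2.5, 19.0)] * 6 + [
            arc_tract(40.0, 2.5, 19.0, flip=True)
        ] * 6
        counts, edges = heading_histogram(
            TractSet(tracts=tracts), axis="x", bin_width=10.0
        )
        np.testing.assert_array_equal(counts, counts[::-1])
        sym = heading_symmetry(TractSet(tracts=tracts))
        assert np.all(sym < 1e-6)

    def test_purse_truth_population_symmetry_within_ten_degrees(self):
        """Truth tracts of the midline-crossing phantom: |mean - 90| < 10 per axis."""
        from myotract.phantom import PhantomSpec, make_geometry

        truth = make_geometry(PhantomSpec(geometry_kind="purse_string", seed=5))
        sym = heading_symmetry(truth.tracts)
        assert np.all(sym < 10.0)

    def test_empty_bundle_rejected(self):
        with pytest.raises(ValueError):
            heading_histogram(TractSet(tracts=[]), axis="x")


class TestCanonicalOrientation:
    def test_mirrored_arcs_get_opposite_traversal(self):
        a = canonical_orientation(arc_tract(40.0, 2.5, 19.0))
        b = canonical_orientation(arc_tract(40.0, 2.5, 19.0, flip=True))
        # a heads +x, b heads -x
        assert (a.points[-1, 0] - a.points[0, 0]) > 0
        assert (b.points[-1, 0] - b.points[0, 0]) < 0

    def test_idempotent(self):
        t = arc_tract(40.0, 2.5, 19.0)
        once = canonical_orientation(t)
        twice = canonical_orientation(once)
        np.testing.assert_array_equal(once.points, twice.points)

    def test_straight_tract_falls_back_to_sign_rule(self):
        fwd = Tract(points=np.linspace([0, 0, 0], [10, 0, 0], 10))
        rev = Tract(points=np.linspace([10, 0, 0], [0, 0, 0], 10))
        a = tract_mean_heading(fwd)
        b = tract_mean_heading(rev)
        np.testing.assert_allclose(a, b, atol=1e-9)
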