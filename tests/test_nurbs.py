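"""Cox–de Boor basis, rational basis, curve evaluation, least-squares
fitting with pinned endpoints, time mapping and closest-point projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import BSpline

from arthroguide.nurbs import (
    NurbsCurve,
    NurbsError,
    RawTrajectory,
    bspline_basis,
    build_knot_vector,
    closest_point,
    closest_point_batch,
    curve_derivatives,
    evaluate_curve,
    fit_curve,
    map_time,
    polyline_turning_angle,
    rational_basis,
    rational_basis_matrix,
    time_parameterize,
)

from conftest import random_curve, straight_segment_curve, trajectory_from_positions

BEZIER2 = [0, 0, 0, 1, 1, 1]  # single-span quadratic (Bernstein) knots


def scipy_rational_eval(curve: NurbsCurve, u):
    """Independent NURBS evaluation: scipy B-spline in homogeneous
    coordinates (weighted points + weight channel), then perspective
    division."""
    w = curve.weights[:, None]
    coeffs = np.hstack([curve.control_points * w, w])
    spl = BSpline(curve.knots, coeffs, curve.degree, extrapolate=False)
    uu = np.atleast_1d(np.asarray(u, float))
    # closed right end: scipy treats the last knot as outside the domain
    vals = spl(np.where(uu == curve.knots[-1], curve.knots[-1] - 1e-14, uu))
    return vals[:, :3] / vals[:, 3:4]


class TestBsplineBasis:
    def test_degree0_indicator(self):
        U = [0, 0.5, 1]
        assert bspline_basis(0, 0, U, 0.3) == 1.0
        assert bspline_basis(1, 0, U, 0.3) == 0.0

    def test_bernstein_midpoint(self):
        vals = [bspline_basis(i, 2, BEZIER2, 0.5) for i in range(3)]
        assert np.allclose(vals, [0.25, 0.5, 0.25])

    def test_index_out_of_range(self):
        with pytest.raises(NurbsError):
            bspline_basis(3, 2, BEZIER2, 0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(u=st.floats(0.0, 1.0), seed=st.integers(0, 1000))
    def test_partition_of_unity(self, u, seed):
        curve = random_curve(np.random.default_rng(seed))
        R = rational_basis_matrix(curve.degree, curve.knots, curve.weights, u)
        assert abs(R.sum() - 1.0) < 1e-12
        assert np.all(R >= -1e-15)


class TestRationalBasis:
    def test_equal_weights_reduce_to_bspline(self):
        for u in (0.0, 0.3, 0.77, 1.0):
            for i in range(3):
                assert np.isclose(
                    rational_basis(i, 2, BEZIER2, [2.0, 2.0, 2.0], u),
                    bspline_basis(i, 2, BEZIER2, u),
                )

    def test_weighted_hand_values(self):
        vals = [rational_basis(i, 2, BEZIER2, [1, 2, 1], 0.5) for i in range(3)]
        assert np.allclose(vals, [1 / 6, 2 / 3, 1 / 6])

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(NurbsError):
            rational_basis(0, 2, BEZIER2, [1, 0, 1], 0.5)


class TestEvaluateCurve:
    def test_coincident_control_points_give_constant(self):
        P = np.tile([1.5, -2.0, 0.5], (4, 1))
        curve = NurbsCurve(3, [0, 0, 0, 0, 1, 1, 1, 1], P, np.ones(4), (0, 1))
        for u in np.linspace(0, 1, 11):
            assert np.allclose(evaluate_curve(curve, u), [1.5, -2.0, 0.5])

    def test_clamped_endpoints(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            curve = random_curve(rng)
            assert np.allclose(evaluate_curve(curve, 0.0), curve.control_points[0])
            assert np.allclose(evaluate_curve(curve, 1.0), curve.control_points[-1])

    def test_collinear_quadratic_midpoint(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        curve = NurbsCurve(2, BEZIER2, P, np.ones(3), (0, 1))
        assert np.allclose(evaluate_curve(curve, 0.5), [1, 0, 0])

    def test_out_of_range_rejected(self):
        curve = random_curve(np.random.default_rng(6))
        with pytest.raises(NurbsError):
            evaluate_curve(curve, 1.2)

    def test_agrees_with_scipy_homogeneous_oracle(self):
        rng = np.random.default_rng(7)
        grid = np.linspace(0, 1, 257)
        for _ in range(20):
            curve = random_curve(rng)
            mine = evaluate_curve(curve, grid)
            oracle = scipy_rational_eval(curve, grid)
            assert np.max(np.abs(mine - oracle)) < 1e-10

    def test_derivatives_match_finite_differences(self):
        rng = np.random.default_rng(8)
        curve = random_curve(rng, p=3, m=8)
        u = np.linspace(0.05, 0.95, 19)
        C, dC, ddC = curve_derivatives(curve, u)
        h = 1e-6
        fd1 = (evaluate_curve(curve, u + h) - evaluate_curve(curve, u - h)) / (2 * h)
        fd2 = (
            evaluate_curve(curve, u + h)
            - 2 * evaluate_curve(curve, u)
            + evaluate_curve(curve, u - h)
        ) / h**2
        assert np.max(np.abs(dC - fd1)) < 1e-5
        assert np.max(np.abs(ddC - fd2)) < 1e-2


class TestTimeParameterize:
    def test_hand_values(self):
        traj = trajectory_from_positions(np.zeros((4, 3)) + np.arange(4)[:, None])
        samples = [s.with_time(t) for s, t in zip(traj.samples, [0.0, 1.0, 2.0, 4.0])]
        traj = RawTrajectory(tuple(samples))
        assert np.allclose(time_parameterize(traj), [0, 0.25, 0.5, 1.0])

    def test_endpoints_exact(self):
        traj = trajectory_from_positions(np.random.default_rng(0).normal(size=(9, 3)))
        ubar = time_parameterize(traj)
        assert ubar[0] == 0.0 and ubar[-1] == 1.0


class TestKnotVector:
    def test_bezier_case_no_interior(self):
        U = build_knot_vector(3, 4, np.linspace(0, 1, 10))
        assert np.array_equal(U, [0, 0, 0, 0, 1, 1, 1, 1])

    def test_interior_strictly_increasing_inside(self):
        U = build_knot_vector(2, 5, np.linspace(0, 1, 20))
        interior = U[3:-3]
        assert len(interior) == 2
        assert np.all(interior > 0) and np.all(interior < 1)
        assert np.all(np.diff(interior) > 0)

    @pytest.mark.parametrize("p,m", [(2, 4), (3, 5), (3, 9)])
    def test_length(self, p, m):
        U = build_knot_vector(p, m, np.linspace(0, 1, 30))
        assert len(U) == m + p + 1

    def test_too_few_control_points(self):
        with pytest.raises(NurbsError):
            build_knot_vector(3, 3, np.linspace(0, 1, 10))


def constrained_lsq_oracle(traj, m, p):
    """Brute-force reference: solve the pinned-endpoint least squares by
    explicit normal equations."""
    ubar = time_parameterize(traj)
    U = build_knot_vector(p, m, ubar)
    R = rational_basis_matrix(p, U, np.ones(m), ubar)
    Q = traj.positions
    A = R[:, 1:-1]
    rhs = Q - np.outer(R[:, 0], Q[0]) - np.outer(R[:, -1], Q[-1])
    interior = np.linalg.solve(A.T @ A, A.T @ rhs)
    return np.vstack([Q[0], interior, Q[-1]])


class TestFitCurve:
    def test_line_reproduced_exactly(self):
        t = np.linspace(0, 1, 20)
        pos = np.outer(t, [3.0, -1.0, 2.0])
        traj = trajectory_from_positions(pos)
        curve = fit_curve(traj, m=4, p=3)
        resid = np.linalg.norm(
            evaluate_curve(curve, time_parameterize(traj)) - pos, axis=1
        )
        assert resid.max() < 1e-9
        assert np.allclose(curve.control_points[0], pos[0])
        assert np.allclose(curve.control_points[-1], pos[-1])

    def test_circle_arc_matches_normal_equation_oracle(self):
        theta = np.linspace(0, np.pi / 2, 100)
        radius = 5.0
        pos = radius * np.column_stack(
            [np.cos(theta), np.sin(theta), np.zeros_like(theta)]
        )
        traj = trajectory_from_positions(pos)
        curve = fit_curve(traj, m=12, p=3)
        resid = np.linalg.norm(
            evaluate_curve(curve, time_parameterize(traj)) - pos, axis=1
        )
        assert resid.max() < 1e-3 * radius
        oracle_P = constrained_lsq_oracle(traj, 12, 3)
        assert np.max(np.abs(curve.control_points - oracle_P)) < 1e-6

    def test_noise_rms_consistent_with_sigma(self):
        theta = np.linspace(0, np.pi / 2, 200)
        pos = 5.0 * np.column_stack(
            [np.cos(theta), np.sin(theta), np.zeros_like(theta)]
        )
        sigma = 0.1
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = trajectory_from_positions(pos + rng.normal(0, sigma, pos.shape))
            curve = fit_curve(noisy, m=12, p=3)
            resid = np.linalg.norm(
                evaluate_curve(curve, time_parameterize(noisy)) - noisy.positions,
                axis=1,
            )
            # per-axis RMS residual of an honest least-squares fit
            ratios.append(np.sqrt(np.mean(resid**2) / 3) / sigma)
        assert 0.5 < np.mean(ratios) < 1.5

    def test_no_compression_rejected(self):
        traj = trajectory_from_positions(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(NurbsError):
            fit_curve(traj, m=10, p=3)

    def test_smoothing_reduces_turning_angle(self, expert_traj):
        rng_master = np.random.default_rng(99)
        smoother = 0
        for _ in range(20):
            noisy = expert_traj.positions + rng_master.normal(
                0, 0.1, (len(expert_traj), 3)
            )
            traj = trajectory_from_positions(noisy)
            curve = fit_curve(traj, m=15, p=3)
            fitted = evaluate_curve(curve, time_parameterize(traj))
            smoother += polyline_turning_angle(fitted) < polyline_turning_angle(noisy)
        assert smoother == 20

    def test_compression_smaller_than_csv(self, expert_traj, tmp_path):
        from arthroguide.io import write_trajectory_csv

        curve = fit_curve(expert_traj, m=len(expert_traj) // 2, p=3)
        csv_path = tmp_path / "raw.csv"
        write_trajectory_csv(csv_path, expert_traj)
        assert len(curve.to_json().encode()) < csv_path.stat().st_size


class TestMapTime:
    def test_window_and_interpolation(self):
        curve = straight_segment_curve()
        curve = NurbsCurve(
            curve.degree, curve.knots, curve.control_points, curve.weights, (2.0, 12.0)
        )
        assert map_time(curve, 0.0) == 2.0
        assert map_time(curve, 1.0) == 12.0
        assert map_time(curve, 0.3) == pytest.approx(5.0)

    def test_strictly_increasing(self):
        curve = straight_segment_curve()
        u = np.linspace(0, 1, 50)
        t = [map_time(curve, x) for x in u]
        assert np.all(np.diff(t) > 0)


class TestClosestPoint:
    def test_self_projection_is_zero(self):
        rng = np.random.default_rng(10)
        curve = random_curve(rng, p=3, m=7)
        for u in (0.12, 0.5, 0.93):
            x = evaluate_curve(curve, u)
            _, _, d = closest_point(curve, x)
            assert d < 1e-8

    def test_segment_projection(self):
        curve = straight_segment_curve((0, 0, 0), (10, 0, 0))
        u, pt, d = closest_point(curve, [3.0, 4.0, 0.0])
        assert abs(u - 0.3) < 1e-6
        assert np.allclose(pt, [3, 0, 0], atol=1e-6)
        assert abs(d - 4.0) < 1e-8

    def test_against_dense_scan_oracle(self):
        rng = np.random.default_rng(11)
        grid = np.linspace(0, 1, 100001)
        for _ in range(5):
            curve = random_curve(rng, p=3)
            pts = evaluate_curve(curve, grid)
            queries = rng.normal(0, 3, (20, 3))
            _, _, dists = closest_point_batch(curve, queries)
            for x, d in zip(queries, dists):
                brute = np.min(np.linalg.norm(pts - x, axis=1))
                assert abs(d - brute) < 1e-4


class TestSerialization:
    def test_json_round_trip_exact(self):
        rng = np.random.default_rng(12)
        curve = random_curve(rng)
        back = NurbsCurve.from_json(curve.to_json())
        assert back.degree == curve.degree
        assert np.array_equal(back.knots, curve.knots)
        assert np.array_equal(back.control_points, curve.control_points)
        assert np.array_equal(back.weights, curve.weights)
        assert back.time_window == curve.time_window

    def test_invalid_constructions_rejected(self):
        with pytest.raises(NurbsError):
            NurbsCurve(3, [0, 0, 0, 0, 1, 1, 1, 1], np.zeros((3, 3)), np.ones(3),
                       (0, 1))
        with pytest.raises(NurbsError):
            NurbsCurve(2, [0, 0, 0, 1, 1, 1], np.zeros((3, 3)),
                       np.array([1.0, -1.0, 1.0]), (0, 1))
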