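"""NURBS representation, least-squares fitting and projection of
arthroscope trajectories.

The recorded trajectory is a sequence of timestamped 3-D points Q_i.  A
degree-p NURBS curve

    C(u) = sum_i R_{i,p}(u) P_i,        u in [0, 1]

with m < n control points P_i smooths the tracking noise and compresses
the data.  Each sample time t_i maps to the chord parameter
u_i = (t_i - t0) / (t1 - t0), so the curve parameter doubles as
normalized recording time: t = t0 + u (t1 - t0).

The basis functions N_{i,p} follow the Cox–de Boor recursion on a
clamped (non-periodic) knot vector; R_{i,p} is the weight-normalized
rational basis.  Fitting pins the first and last control points to the
first and last data points and solves the interior control points by
linear least squares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .tracking import TrackedSample

__all__ = [
    "RawTrajectory",
    "NurbsCurve",
    "NurbsError",
    "bspline_basis",
    "bspline_basis_matrix",
    "rational_basis",
    "rational_basis_matrix",
    "evaluate_curve",
    "curve_derivatives",
    "time_parameterize",
    "build_knot_vector",
    "fit_curve",
    "map_time",
    "closest_point",
    "closest_point_batch",
    "polyline_turning_angle",
]


class NurbsError(ValueError):
    """Invalid NURBS construction or evaluation request."""


@dataclass(frozen=True)
class RawTrajectory:
    """Ordered tracked samples with the recording window [t0, t1]."""

    samples: tuple[TrackedSample, ...]

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        if len(samples) < 2:
            raise NurbsError("trajectory needs at least 2 samples")
        times = np.array([s.time for s in samples])
        if np.any(np.diff(times) <= 0):
            raise NurbsError("trajectory times must be strictly increasing")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def t0(self) -> float:
        return self.samples[0].time

    @property
    def t1(self) -> float:
        return self.samples[-1].time

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.samples])

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.samples])

    @property
    def quaternions(self) -> np.ndarray:
        return np.array([s.orientation for s in self.samples])

    @property
    def sources(self) -> list[str]:
        return [s.source for s in self.samples]


@dataclass(frozen=True)
class NurbsCurve:
    """Degree, clamped knots, weighted control points and time window."""

    degree: int
    knots: np.ndarray
    control_points: np.ndarray
    weights: np.ndarray
    time_window: tuple[float, float]

    def __post_init__(self) -> None:
        p = int(self.degree)
        U = np.asarray(self.knots, dtype=float)
        P = np.asarray(self.control_points, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if P.ndim != 2 or P.shape[1] != 3:
            raise NurbsError("control points must be an (m, 3) array")
        m = P.shape[0]
        if m <= p:
            raise NurbsError(f"need more than degree={p} control points, got {m}")
        if U.shape != (m + p + 1,):
            raise NurbsError(f"knot vector must have m+p+1={m + p + 1} entries")
        if np.any(np.diff(U) < 0):
            raise NurbsError("knot vector must be non-decreasing")
        if not (np.allclose(U[: p + 1], U[0]) and np.allclose(U[-(p + 1):], U[-1])):
            raise NurbsError("knot vector must be clamped (p+1-fold end knots)")
        if U[p + 1] <= U[0] or U[-(p + 2)] >= U[-1]:
            raise NurbsError("end knots repeated more than p+1 times")
        if w.shape != (m,) or np.any(w <= 0):
            raise NurbsError("weights must be m positive scalars")
        object.__setattr__(self, "degree", p)
        object.__setattr__(self, "knots", U)
        object.__setattr__(self, "control_points", P)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "time_window", (float(self.time_window[0]),
                                                 float(self.time_window[1])))

    @property
    def n_control_points(self) -> int:
        return self.control_points.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "degree": self.degree,
                "knots": self.knots.tolist(),
                "control_points": self.control_points.tolist(),
                "weights": self.weights.tolist(),
                "t0": self.time_window[0],
                "t1": self.time_window[1],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NurbsCurve":
        d = json.loads(text)
        return cls(
            degree=d["degree"],
            knots=np.array(d["knots"]),
            control_points=np.array(d["control_points"]),
            weights=np.array(d["weights"]),
            time_window=(d["t0"], d["t1"]),
        )


def bspline_basis_matrix(p: int, U: np.ndarray, u) -> np.ndarray:
    """All B-spline basis values N_{i,p}(u) by the Cox–de Boor recursion.

    Returns an array of shape (len(u), len(U)-p-1).  0/0 terms in the
    recursion are taken as 0; the curve domain is closed at the right
    end, so u equal to the final knot activates the last span.
    """
    U = np.asarray(U, dtype=float)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    nb = len(U) - 1  # number of degree-0 functions
    if nb < p + 1:
        raise NurbsError("knot vector too short for requested degree")

    # degree 0: half-open indicator [U_i, U_{i+1})
    N = ((U[:-1][None, :] <= u[:, None]) & (u[:, None] < U[1:][None, :])).astype(float)
    # close the right end of the domain: u == U[-1] lands in the last
    # non-empty span
    at_end = u == U[-1]
    if np.any(at_end):
        last = np.nonzero(np.diff(U) > 0)[0][-1]
        N[at_end, :] = 0.0
        N[at_end, last] = 1.0

    for d in range(1, p + 1):
        left_den = U[d:-1] - U[: -d - 1]
        right_den = U[d + 1:] - U[1:-d]
        with np.errstate(divide="ignore", invalid="ignore"):
            left = np.where(
                left_den > 0, (u[:, None] - U[None, : -d - 1]) / left_den, 0.0
            )
            right = np.where(
                right_den > 0, (U[None, d + 1:] - u[:, None]) / right_den, 0.0
            )
        N = left * N[:, :-1] + right * N[:, 1:]
    return N


def bspline_basis(i: int, p: int, U, u: float) -> float:
    """Single basis value N_{i,p}(u)."""
    U = np.asarray(U, dtype=float)
    n_basis = len(U) - p - 1
    if not 0 <= i < n_basis:
        raise NurbsError(f"basis index out of range: i={i}, have {n_basis} functions")
    return float(bspline_basis_matrix(p, U, u)[0, i])


def rational_basis_matrix(p: int, U, weights, u) -> np.ndarray:
    """All rational basis values R_{i,p}(u) = N_{i,p} w_i / sum_j N_{j,p} w_j."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise NurbsError("invalid weight: weights must be strictly positive")
    N = bspline_basis_matrix(p, U, u)
    Nw = N * w[None, :]
    return Nw / Nw.sum(axis=1, keepdims=True)


def rational_basis(i: int, p: int, U, weights, u: float) -> float:
    """Single rational basis value R_{i,p}(u)."""
    U = np.asarray(U, dtype=float)
    n_basis = len(U) - p - 1
    if not 0 <= i < n_basis:
        raise NurbsError(f"basis index out of range: i={i}, have {n_basis} functions")
    return float(rational_basis_matrix(p, U, weights, u)[0, i])


def _check_param(u) -> np.ndarray:
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if np.any(u < 0) or np.any(u > 1):
        raise NurbsError("parameter out of range: u must lie in [0, 1]")
    return u


def evaluate_curve(curve: NurbsCurve, u):
    """Evaluate C(u) = sum_i R_{i,p}(u) P_i for scalar or array u in [0, 1]."""
    scalar = np.isscalar(u) or np.ndim(u) == 0
    uu = _check_param(u)
    R = rational_basis_matrix(curve.degree, curve.knots, curve.weights, uu)
    pts = R @ curve.control_points
    return pts[0] if scalar else pts


def _basis_derivative_matrices(p: int, U: np.ndarray, u: np.ndarray):
    """N, N' and N'' matrices for degree p at parameters u.

    Derivatives follow N'_{i,p} = p [ N_{i,p-1}/(U_{i+p}-U_i)
    - N_{i+1,p-1}/(U_{i+p+1}-U_{i+1}) ] with 0/0 terms as 0.
    """
    U = np.asarray(U, dtype=float)

    def deriv(Nlow: np.ndarray, d: int) -> np.ndarray:
        # Nlow: degree d-1 matrix with len(U)-d columns
        den1 = U[d:-1] - U[: -d - 1]
        den2 = U[d + 1:] - U[1:-d]
        a = np.where(den1 > 0, d / np.where(den1 > 0, den1, 1.0), 0.0)
        b = np.where(den2 > 0, d / np.where(den2 > 0, den2, 1.0), 0.0)
        return a[None, :] * Nlow[:, :-1] - b[None, :] * Nlow[:, 1:]

    if p < 1:
        N = bspline_basis_matrix(p, U, u)
        z = np.zeros_like(N)
        return N, z, z
    if p < 2:
        N1 = bspline_basis_matrix(p - 1, U, u)
        N = bspline_basis_matrix(p, U, u)
        d1 = deriv(N1, p)
        return N, d1, np.zeros_like(N)
    Np2 = bspline_basis_matrix(p - 2, U, u)
    Np1 = bspline_basis_matrix(p - 1, U, u)
    N = bspline_basis_matrix(p, U, u)
    dNp1 = deriv(Np2, p - 1)
    dN = deriv(Np1, p)
    ddN = deriv(dNp1, p)
    return N, dN, ddN


def curve_derivatives(curve: NurbsCurve, u):
    """C(u), C'(u), C''(u) for array u, via the rational quotient rule."""
    uu = _check_param(u)
    N, dN, ddN = _basis_derivative_matrices(curve.degree, curve.knots, uu)
    w = curve.weights
    P = curve.control_points
    Aw = (N * w) @ P
    W = (N * w).sum(axis=1, keepdims=True)
    dAw = (dN * w) @ P
    dW = (dN * w).sum(axis=1, keepdims=True)
    ddAw = (ddN * w) @ P
    ddW = (ddN * w).sum(axis=1, keepdims=True)
    C = Aw / W
    dC = (dAw - dW * C) / W
    ddC = (ddAw - 2 * dW * dC - ddW * C) / W
    return C, dC, ddC


def time_parameterize(traj: RawTrajectory) -> np.ndarray:
    """Chord parameters u_i = (t_i - t0) / (t1 - t0)."""
    t = traj.times
    if t[-1] == t[0]:
        raise NurbsError("degenerate time window: t1 == t0")
    return (t - t[0]) / (t[-1] - t[0])


def build_knot_vector(p: int, m: int, ubar: np.ndarray) -> np.ndarray:
    """Clamped knot vector with interior knots placed by parameter averaging.

    p+1 zeros, m-p-1 interior knots, p+1 ones.  Interior knot j averages
    the data parameters in a sliding window (the standard placement for
    least-squares approximation), which keeps every basis function
    supported on data and the fit well conditioned.
    """
    if m <= p:
        raise NurbsError(f"too few control points: need m > p, got m={m}, p={p}")
    ubar = np.asarray(ubar, dtype=float)
    n = len(ubar)
    n_interior = m - p - 1
    interior = np.empty(n_interior)
    d = n / (m - p)
    for j in range(1, n_interior + 1):
        i = int(np.floor(j * d))
        alpha = j * d - i
        interior[j - 1] = (1 - alpha) * ubar[i - 1] + alpha * ubar[i]
    if n_interior and (
        np.any(np.diff(interior) <= 0) or interior[0] <= 0 or interior[-1] >= 1
    ):
        raise NurbsError("interior knots not strictly increasing inside (0, 1)")
    return np.concatenate([np.zeros(p + 1), interior, np.ones(p + 1)])


def fit_curve(
    traj: RawTrajectory,
    m: int,
    p: int = 3,
    weights: np.ndarray | None = None,
) -> NurbsCurve:
    """Least-squares NURBS fit with pinned endpoints.

    The first and last control points are fixed to the first and last
    data points; the m-2 interior control points minimize
    sum_i ||C(u_i) - Q_i||^2 over the chord parameters u_i.  Each
    coordinate is fit against the same rational collocation matrix.
    Weights are fixed inputs (default 1), never optimized.
    """
    n = len(traj)
    if m >= n:
        raise NurbsError(f"no compression: need m < n, got m={m}, n={n}")
    if m < p + 1:
        raise NurbsError(f"too few control points: need m >= p+1, got m={m}, p={p}")
    w = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (m,) or np.any(w <= 0):
        raise NurbsError("invalid weight: need m positive weights")

    ubar = time_parameterize(traj)
    U = build_knot_vector(p, m, ubar)
    Q = traj.positions
    R = rational_basis_matrix(p, U, w, ubar)

    # pin endpoints, solve the interior by least squares
    rhs = Q - np.outer(R[:, 0], Q[0]) - np.outer(R[:, -1], Q[-1])
    A = R[:, 1:-1]
    if m > 2:
        sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
        if rank < m - 2:
            raise NurbsError("ill-conditioned fit: collocation matrix is rank deficient")
        P = np.vstack([Q[0], sol, Q[-1]])
    else:
        P = np.vstack([Q[0], Q[-1]])
    return NurbsCurve(p, U, P, w, (traj.t0, traj.t1))


def map_time(curve: NurbsCurve, u: float) -> float:
    """Recording time for a curve parameter: t = t0 + u (t1 - t0)."""
    t0, t1 = curve.time_window
    return t0 + float(u) * (t1 - t0)


def _newton_refine(curve: NurbsCurve, x: np.ndarray, u0: float,
                   lo: float, hi: float) -> float:
    """Newton iteration on g(u) = ||C(u) - x||^2, golden-section fallback."""
    u = u0
    for _ in range(50):
        C, dC, ddC = curve_derivatives(curve, np.array([u]))
        diff = C[0] - x
        g1 = 2.0 * diff @ dC[0]
        g2 = 2.0 * (dC[0] @ dC[0] + diff @ ddC[0])
        if g2 <= 0:
            break
        step = g1 / g2
        u_new = min(max(u - step, lo), hi)
        if abs(u_new - u) < 1e-10:
            return u_new
        u = u_new
    else:
        return u
    # fallback: golden-section search on the bracket
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda v: float(np.sum((evaluate_curve(curve, v) - x) ** 2)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def closest_point(
    curve: NurbsCurve, x, n_scan: int = 512
) -> tuple[float, np.ndarray, float]:
    """Orthogonal projection of x onto the curve.

    Coarse scan over n_scan parameters followed by Newton refinement of
    the squared distance; ties in the scan break toward the smaller
    parameter.  Returns (u*, C(u*), distance).
    """
    x = np.asarray(x, dtype=float).reshape(3)
    grid = np.linspace(0.0, 1.0, n_scan)
    pts = evaluate_curve(curve, grid)
    d2 = np.sum((pts - x) ** 2, axis=1)
    k = int(np.argmin(d2))  # argmin returns the first (smallest-u) minimizer
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_scan - 1)]
    u = _newton_refine(curve, x, grid[k], lo, hi)
    pt = evaluate_curve(curve, u)
    dist = float(np.linalg.norm(pt - x))
    # a refinement that somehow went uphill falls back to the scan point
    if dist > np.sqrt(d2[k]) + 1e-12:
        u, pt, dist = grid[k], pts[k], float(np.sqrt(d2[k]))
    return float(u), pt, dist


def closest_point_batch(
    curve: NurbsCurve, points: np.ndarray, n_scan: int = 512
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized closest-point projection for many query points.

    Shares one parameter scan across all queries and runs the Newton
    refinement on all of them simultaneously; queries whose Newton
    iteration stalls fall back to the scalar path.  Returns
    (u*, projected points, distances).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    nq = len(points)
    grid = np.linspace(0.0, 1.0, n_scan)
    pts = evaluate_curve(curve, grid)
    d2 = (
        np.sum(points**2, axis=1)[:, None]
        - 2.0 * points @ pts.T
        + np.sum(pts**2, axis=1)[None, :]
    )
    k = np.argmin(d2, axis=1)
    scan_d = np.sqrt(np.maximum(d2[np.arange(nq), k], 0.0))
    lo = grid[np.maximum(k - 1, 0)]
    hi = grid[np.minimum(k + 1, n_scan - 1)]
    u = grid[k].copy()
    active = np.ones(nq, dtype=bool)
    stalled = np.zeros(nq, dtype=bool)
    for _ in range(50):
        if not active.any():
            break
        C, dC, ddC = curve_derivatives(curve, u[active])
        diff = C - points[active]
        g1 = 2.0 * np.einsum("ij,ij->i", diff, dC)
        g2 = 2.0 * (np.einsum("ij,ij->i", dC, dC) + np.einsum("ij,ij->i", diff, ddC))
        bad = g2 <= 0
        idx = np.nonzero(active)[0]
        stalled[idx[bad]] = True
        active[idx[bad]] = False
        good = idx[~bad]
        if good.size == 0:
            continue
        step = g1[~bad] / g2[~bad]
        u_new = np.clip(u[good] - step, lo[good], hi[good])
        done = np.abs(u_new - u[good]) < 1e-10
        u[good] = u_new
        active[good[done]] = False
    for j in np.nonzero(stalled)[0]:
        u[j] = _newton_refine(curve, points[j], grid[k[j]], lo[j], hi[j])
    proj = evaluate_curve(curve, u)
    dist = np.linalg.norm(proj - points, axis=1)
    worse = dist > scan_d + 1e-12
    if np.any(worse):
        u[worse] = grid[k[worse]]
        proj[worse] = pts[k[worse]]
        dist[worse] = scan_d[worse]
    return u, proj, dist


def polyline_turning_angle(points: np.ndarray) -> float:
    """Total turning angle (radians) of a polyline; a discrete curvature
    measure used to compare raw and smoothed trajectories."""
    points = np.asarray(points, dtype=float)
    seg = np.diff(points, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    keep = norms > 1e-12
    seg = seg[keep] / norms[keep][:, None]
    cosang = np.clip(np.einsum("ij,ij->i", seg[:-1], seg[1:]), -1.0, 1.0)
    return float(np.sum(np.arccos(cosang)))
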