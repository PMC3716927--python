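import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from arthroguide.nurbs import NurbsCurve, RawTrajectory, fit_curve
from arthroguide.simulate import ExpertPathParams, generate_expert_trajectory
from arthroguide.tracking import RigidTransform, TrackedSample


@pytest.fixture(scope="session")
def expert_traj() -> RawTrajectory:
    return generate_expert_trajectory(ExpertPathParams(seed=3))


@pytest.fixture(scope="session")
def expert_curve(expert_traj) -> NurbsCurve:
    return fit_curve(expert_traj, m=15, p=3)


def random_rigid_transform(rng, max_angle=1.0, trans_scale=5.0) -> RigidTransform:
    R = Rotation.from_rotvec(rng.normal(0, max_angle / 3, 3)).as_matrix()
    t = rng.uniform(-trans_scale, trans_scale, 3)
    return RigidTransform(R, t)


def random_curve(rng, p=None, m=None) -> NurbsCurve:
    """A random valid clamped NURBS curve for property tests."""
    p = int(rng.integers(2, 5)) if p is None else p
    m = int(rng.integers(p + 1, p + 8)) if m is None else m
    n_interior = m - p - 1
    gaps = rng.uniform(0.2, 1.0, n_interior + 1)
    interior = np.cumsum(gaps)[:-1] / np.sum(gaps)
    knots = np.concatenate([np.zeros(p + 1), interior, np.ones(p + 1)])
    ctrl = rng.normal(0, 3, (m, 3))
    weights = rng.uniform(0.5, 2.0, m)
    return NurbsCurve(p, knots, ctrl, weights, (0.0, 10.0))


def straight_segment_curve(start=(0.0, 0.0, 0.0), end=(10.0, 0.0, 0.0),
                           p=1) -> NurbsCurve:
    """Degree-1 curve tracing the segment from start to end."""
    start, end = np.asarray(start, float), np.asarray(end, float)
    return NurbsCurve(
        p,
        np.concatenate([np.zeros(p + 1), np.ones(p + 1)]),
        np.linspace(start, end, p + 1),
        np.ones(p + 1),
        (0.0, 10.0),
    )


def trajectory_from_positions(positions, dt=1.0 / 30.0) -> RawTrajectory:
    q = np.array([1.0, 0.0, 0.0, 0.0])
    return RawTrajectory(
        tuple(
            TrackedSample(i * dt, p, q, source="left")
            for i, p in enumerate(np.asarray(positions, float))
        )
    )
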