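"""Synthetic data: expert inspection paths, optical-tracker noise, and a
simulated trainee operating the (virtual) haptic stylus.

The generator stands in for three physical components so the whole
training pipeline runs on a desk with no hardware:

* an expert inspection path — a smooth spline through random waypoints
  inside a knee-scale workspace, sampled at the tracker frame rate;
* the optical tracker — additive Gaussian position noise plus frame
  dropouts that repeat the previous sample (marker not detected);
* the trainee — a damped point mass pulled toward a target that
  advances along the expert curve, with Gaussian "intent" noise whose
  standard deviation encodes (lack of) skill, plus the guidance force.

Everything is deterministic given its seed.  None of the operator
parameters are estimates of human subjects; they are synthetic dials
that produce qualitatively trainee-like behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .guidance import GuidanceConfig, GuidanceState, guidance_step
from .nurbs import NurbsCurve, RawTrajectory, evaluate_curve
from .tracking import TrackedSample

__all__ = [
    "ExpertPathParams",
    "TrackerNoiseParams",
    "OperatorModel",
    "SimulationDiverged",
    "generate_expert_trajectory",
    "add_tracking_noise",
    "simulate_session",
    "subject_seed",
]

FRAME_DT = 1.0 / 30.0  # tracker capture interval (30 frames per second)


class SimulationDiverged(RuntimeError):
    """The integrated probe state became non-finite."""


@dataclass(frozen=True)
class ExpertPathParams:
    """Shape of the synthetic expert inspection path.

    ``workspace_extent`` is the full width of the axis-aligned workspace
    box (cm), centred at the origin — default 10×8×6 cm, a knee-joint
    scale.  ``smoothness`` in [0, 1) blends each interior waypoint
    toward its neighbours' midpoint before spline interpolation, taming
    sharp turns.
    """

    workspace_extent: tuple[float, float, float] = (10.0, 8.0, 6.0)
    n_waypoints: int = 8
    duration: float = 15.0
    smoothness: float = 0.5
    frame_rate: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_waypoints < 4:
            raise ValueError("need at least 4 waypoints")
        if not 0 <= self.smoothness < 1:
            raise ValueError("smoothness must lie in [0, 1)")


@dataclass(frozen=True)
class TrackerNoiseParams:
    """Optical-tracker imperfections: noise SD (cm), dropout rate, frame rate."""

    sigma: float = 0.05
    dropout_prob: float = 0.02
    frame_rate: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must lie in [0, 1)")


@dataclass(frozen=True)
class OperatorModel:
    """Damped point-mass trainee holding the stylus.

    The operator pulls the probe toward its intended target with a
    proportional gain set for critical damping (gain = damping²/4·mass),
    so ``damping`` doubles as a competence dial: larger damping means a
    stiffer, more decisive operator.  ``skill_sigma`` is the SD (cm) of
    Gaussian noise on where the operator thinks the target is;
    ``speed_factor`` scales how fast the target advances relative to
    the recorded pacing.
    """

    mass: float = 1.0
    damping: float = 8.0
    skill_sigma: float = 0.3
    speed_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.damping <= 0:
            raise ValueError("mass and damping must be positive")

    @property
    def gain(self) -> float:
        return self.damping**2 / (4.0 * self.mass)


def _tangent_quaternions(positions: np.ndarray) -> np.ndarray:
    """Unit quaternions (w,x,y,z) aligning +z with the path tangent."""
    tang = np.gradient(positions, axis=0)
    norms = np.linalg.norm(tang, axis=1)
    quats = np.empty((len(positions), 4))
    z = np.array([0.0, 0.0, 1.0])
    for i, (t, n) in enumerate(zip(tang, norms)):
        if n < 1e-12:
            quats[i] = [1.0, 0.0, 0.0, 0.0]
            continue
        t = t / n
        axis = np.cross(z, t)
        s = np.linalg.norm(axis)
        c = float(z @ t)
        if s < 1e-12:
            quats[i] = [1.0, 0.0, 0.0, 0.0] if c > 0 else [0.0, 1.0, 0.0, 0.0]
            continue
        angle = np.arctan2(s, c)
        x, y, zz, w = Rotation.from_rotvec(axis / s * angle).as_quat()
        quats[i] = [w, x, y, zz]
    return quats


def generate_expert_trajectory(params: ExpertPathParams) -> RawTrajectory:
    """Smooth synthetic expert path sampled at the tracker frame rate.

    Random waypoints are drawn inside 80% of the workspace box, blended
    by the smoothness factor, and interpolated by a natural cubic
    spline over the recording duration; the result is rescaled if
    spline overshoot leaves the box.
    """
    rng = np.random.default_rng(params.seed)
    ext = np.asarray(params.workspace_extent, dtype=float)
    way = rng.uniform(-0.4 * ext, 0.4 * ext, size=(params.n_waypoints, 3))
    if params.smoothness > 0:
        s = params.smoothness
        for _ in range(2):
            mid = 0.5 * (way[:-2] + way[2:])
            way[1:-1] = (1 - s) * way[1:-1] + s * mid
    t_way = np.linspace(0.0, params.duration, params.n_waypoints)
    spline = CubicSpline(t_way, way, axis=0, bc_type="natural")

    n = int(round(params.duration * params.frame_rate))
    times = np.arange(n) / params.frame_rate
    pos = spline(times)
    # rescale into the box if the spline overshoots between waypoints
    over = np.max(2.0 * np.abs(pos) / ext)
    if over > 1.0:
        pos = pos / over
    quats = _tangent_quaternions(pos)
    samples = [
        TrackedSample(float(t), p, q, source="left")
        for t, p, q in zip(times, pos, quats)
    ]
    return RawTrajectory(tuple(samples))


def add_tracking_noise(
    traj: RawTrajectory, noise: TrackerNoiseParams
) -> RawTrajectory:
    """Corrupt a trajectory with tracker noise and hold-last-sample dropouts.

    Each frame independently receives Gaussian position noise (per-axis
    SD ``sigma``); with probability ``dropout_prob`` a frame is instead
    replaced by the previous output frame and marked ``held``.  The
    first frame is never dropped (there is nothing to hold).
    """
    rng = np.random.default_rng(noise.seed)
    pos = traj.positions + rng.normal(0.0, noise.sigma, (len(traj), 3))
    drop = rng.random(len(traj)) < noise.dropout_prob
    drop[0] = False
    out: list[TrackedSample] = []
    for i, s in enumerate(traj.samples):
        if drop[i]:
            prev = out[-1]
            out.append(
                TrackedSample(s.time, prev.position, prev.orientation, source="held")
            )
        else:
            out.append(TrackedSample(s.time, pos[i], s.orientation, source=s.source))
    return RawTrajectory(tuple(out))


def simulate_session(
    curve: NurbsCurve,
    operator: OperatorModel,
    cfg: GuidanceConfig,
    seed: int | None = None,
) -> tuple[RawTrajectory, float]:
    """Run one training session of a simulated trainee along an expert curve.

    The probe is a damped point mass integrated by semi-implicit Euler
    at the 30 Hz tracker rate.  Each step the operator pulls the probe
    toward a noisy view of a target that advances along the curve at
    ``speed_factor`` times the recorded pacing, and the guidance force
    from the configured mode is added.  After the target reaches the end
    of the recording, the session runs on (up to 10 s) until the probe
    settles within the guidance dead zone of the final curve point;
    the elapsed simulated time is the operation time.
    """
    rng = np.random.default_rng(operator.seed if seed is None else seed)
    t0, t1 = curve.time_window
    follow_duration = (t1 - t0) / operator.speed_factor
    dt = FRAME_DT
    k_op = operator.gain

    pos = evaluate_curve(curve, 0.0).copy()
    vel = np.zeros(3)
    state = GuidanceState()
    end_point = evaluate_curve(curve, 1.0)

    samples: list[TrackedSample] = []
    ident = np.array([1.0, 0.0, 0.0, 0.0])
    t = 0.0
    step = 0
    max_time = follow_duration + 10.0
    while True:
        samples.append(TrackedSample(t, pos.copy(), ident, source="left"))
        if t >= follow_duration and (
            np.linalg.norm(pos - end_point) <= cfg.d_t or t >= max_time
        ):
            break
        u_target = min(t / follow_duration, 1.0)
        target = evaluate_curve(curve, u_target)
        intent = target + rng.normal(0.0, operator.skill_sigma, 3)
        F_op = k_op * (intent - pos)
        F_guide, state = guidance_step(state, curve, pos, t, cfg)
        acc = (F_op + F_guide - operator.damping * vel) / operator.mass
        vel = vel + acc * dt
        pos = pos + vel * dt
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(vel))):
            raise SimulationDiverged(f"simulation diverged at step {step} (t={t:.3f}s)")
        step += 1
        t = step * dt

    return RawTrajectory(tuple(samples)), samples[-1].time


def subject_seed(master_seed: int, subject_id: int) -> int:
    """Per-subject RNG seed derived from the cohort master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(subject_id)])
    return int(ss.generate_state(1)[0] % (2**31))
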