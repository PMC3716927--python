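"""Virtual-fixture force guidance along a recorded expert trajectory.

Three force laws act on the trainee's probe position D:

* attractive force — during initialization, pulls the probe toward the
  trajectory start C(t0): constant magnitude k_A·d_A beyond radius d_A,
  proportional (k_A·r) between d_t and d_A, zero inside the dead-zone
  radius d_t;
* static force — tracking-phase guidance with no time pressure:
  k_s times the contour error, the vector from D to its closest point
  on the curve;
* time-dependent force — tracking-phase guidance that also replays the
  expert's pacing: k_d times the tracking error, the vector from D to
  the time-scheduled target point C(t_t).

A training-strength parameter v in [0, 1] scales any of these by
(1 - v): v = 0 is full guidance, v = 1 removes guidance entirely.

Force units are device-normalized (stiffness × cm); no Newton
calibration is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .nurbs import NurbsCurve, closest_point, evaluate_curve

__all__ = [
    "GuidanceConfig",
    "GuidanceState",
    "GuidanceError",
    "attractive_force",
    "static_force",
    "time_dependent_force",
    "apply_training_strength",
    "guidance_step",
]

logger = logging.getLogger(__name__)


class GuidanceError(ValueError):
    """Invalid guidance configuration or request."""


@dataclass(frozen=True)
class GuidanceConfig:
    """Force-law parameters.

    Stiffnesses are in force units per cm, radii in cm.  The default
    stiffnesses and radii are engineering choices for a knee-scale
    workspace; they are configuration values, not published constants.
    """

    k_A: float = 5.0        # attractive stiffness
    d_A: float = 1.0        # outer attraction radius
    d_t: float = 0.1        # inner dead-zone radius
    k_s: float = 5.0        # static (contour) stiffness
    k_d: float = 5.0        # time-dependent (tracking) stiffness
    v: float = 0.0          # training strength: 0 = full guidance, 1 = none
    mode: str = "static"    # "static" | "time_dependent"
    smooth_dead_zone: bool = False
    playback_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.d_t < self.d_A:
            raise GuidanceError("radii must satisfy 0 < d_t < d_A")
        if min(self.k_A, self.k_s, self.k_d) < 0:
            raise GuidanceError("stiffnesses must be non-negative")
        if not 0 <= self.v <= 1:
            raise GuidanceError("invalid training strength: v must lie in [0, 1]")
        if self.mode not in ("static", "time_dependent"):
            raise GuidanceError(f"unknown guidance mode {self.mode!r}")
        if self.playback_rate <= 0:
            raise GuidanceError("playback rate must be positive")


@dataclass(frozen=True)
class GuidanceState:
    """Phase of one guidance session.

    The session starts in ``initialization`` (attraction toward the
    trajectory start) and switches irreversibly to ``tracking`` once the
    probe enters the dead zone around C(t0).  ``tracking_since`` is the
    wall-clock time of the transition and anchors the time-dependent
    target replay.
    """

    phase: str = "initialization"
    tracking_since: float | None = None

    def __post_init__(self) -> None:
        if self.phase not in ("initialization", "tracking"):
            raise GuidanceError(f"unknown phase {self.phase!r}")


def attractive_force(anchor, D, cfg: GuidanceConfig) -> np.ndarray:
    """Initialization force pulling the probe toward the curve start.

    Saturates at magnitude k_A·d_A outside d_A, decreases linearly with
    distance inside, and vanishes inside the dead zone d_t (optionally
    ramped to zero instead of stepping, when ``smooth_dead_zone``).
    """
    delta = np.asarray(anchor, dtype=float) - np.asarray(D, dtype=float)
    r = float(np.linalg.norm(delta))
    if r == 0.0:
        return np.zeros(3)
    if r > cfg.d_A:
        return cfg.k_A * cfg.d_A * delta / r
    if r >= cfg.d_t:
        return cfg.k_A * delta
    if cfg.smooth_dead_zone:
        return cfg.k_A * delta * (r / cfg.d_t)
    return np.zeros(3)


def static_force(curve: NurbsCurve, D, cfg: GuidanceConfig) -> np.ndarray:
    """Contour-error force k_s·(C(u*) - D) toward the closest curve point."""
    _, target, _ = closest_point(curve, D)
    return cfg.k_s * (target - np.asarray(D, dtype=float))


def time_dependent_force(
    curve: NurbsCurve, t_t: float, D, cfg: GuidanceConfig
) -> np.ndarray:
    """Tracking-error force k_d·(C(u(t_t)) - D) toward the scheduled target."""
    t0, t1 = curve.time_window
    if not t0 <= t_t <= t1:
        logger.warning(
            "target time %.6f outside recording window [%.6f, %.6f]; clamped",
            t_t, t0, t1,
        )
        t_t = min(max(t_t, t0), t1)
    u = (t_t - t0) / (t1 - t0)
    target = evaluate_curve(curve, u)
    return cfg.k_d * (target - np.asarray(D, dtype=float))


def apply_training_strength(F, v: float) -> np.ndarray:
    """Scale a guidance force by (1 - v); v=0 full guidance, v=1 none."""
    if not 0 <= v <= 1:
        raise GuidanceError("invalid training strength: v must lie in [0, 1]")
    return (1.0 - v) * np.asarray(F, dtype=float)


def guidance_step(
    state: GuidanceState,
    curve: NurbsCurve,
    D,
    now: float,
    cfg: GuidanceConfig,
) -> tuple[np.ndarray, GuidanceState]:
    """One guidance update: dispatch on phase and mode, scale by strength.

    Initialization attracts the probe to C(t0) and hands over to the
    tracking phase once the probe is inside the dead zone; tracking
    applies the static or time-dependent law.  The time-dependent target
    replays the recording clock from the moment tracking began, scaled
    by ``playback_rate``.
    """
    D = np.asarray(D, dtype=float)
    if state.phase == "initialization":
        start = evaluate_curve(curve, 0.0)
        r = float(np.linalg.norm(start - D))
        if r <= cfg.d_t:
            state = GuidanceState(phase="tracking", tracking_since=now)
        else:
            F = attractive_force(start, D, cfg)
            return apply_training_strength(F, cfg.v), state

    if cfg.mode == "static":
        F = static_force(curve, D, cfg)
    else:
        t0, _ = curve.time_window
        t_t = t0 + (now - state.tracking_since) * cfg.playback_rate
        F = time_dependent_force(curve, t_t, D, cfg)
    return apply_training_strength(F, cfg.v), state
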