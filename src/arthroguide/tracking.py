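"""Rigid-transform and two-camera marker tracking geometry.

A square fiducial marker of known side length is rigidly attached to the
arthroscope and observed by two fixed CCD cameras.  Each detected set of
four corner pixels yields the camera-from-marker extrinsic transform; the
left camera is the reference frame of the recorded trajectory, and poses
recovered from the right camera are chained through the fixed
right-from-left transform ``T_rl``.  When neither camera sees the marker
the previous sample is held.

All coordinate frames are right-handed; positions are in cm, quaternions
are stored w-first.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "CameraIntrinsics",
    "MarkerObservation",
    "TrackedSample",
    "StereoRig",
    "TrackingError",
    "BehindCameraError",
    "PoseEstimationError",
    "NoPoseAvailableError",
    "transform_point",
    "project_to_screen",
    "relative_camera_transform",
    "estimate_pose_from_square",
    "resolve_marker_pose",
    "marker_corners",
    "synthesize_observation",
]

_ORTHO_TOL = 1e-9


class TrackingError(ValueError):
    """Base error for the tracking-geometry module."""


class BehindCameraError(TrackingError):
    """Point has non-positive depth and cannot be projected."""


class PoseEstimationError(TrackingError):
    """Marker corner configuration does not determine a pose."""


class NoPoseAvailableError(TrackingError):
    """Neither camera sees the marker and no previous sample exists."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: ``p -> rotation @ p + translation``.

    Houses both camera extrinsics (camera-from-marker) and inter-camera
    transforms.  Translation is in cm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise TrackingError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise TrackingError("rotation matrix is improper (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_quaternion(cls, quat_wxyz, translation) -> "RigidTransform":
        w, x, y, z = np.asarray(quat_wxyz, dtype=float)
        R = Rotation.from_quat([x, y, z, w]).as_matrix()
        return cls(R, translation)

    def quaternion(self) -> np.ndarray:
        """Rotation as a unit quaternion (w, x, y, z), w >= 0."""
        x, y, z, w = Rotation.from_matrix(self.rotation).as_quat()
        q = np.array([w, x, y, z])
        if q[0] < 0:
            q = -q
        return q

    def inverse(self) -> "RigidTransform":
        RT = self.rotation.T
        return RigidTransform(RT, -RT @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def apply(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return p @ self.rotation.T + self.translation


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole projection matrix K (pixels) and image size (w, h)."""

    matrix: np.ndarray
    image_size: tuple[int, int] = (640, 480)

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        object.__setattr__(self, "matrix", K)
        if K[0, 0] <= 0 or K[1, 1] <= 0:
            raise TrackingError("focal lengths must be strictly positive")
        w, h = self.image_size
        cx, cy = K[0, 2], K[1, 2]
        if not (0 <= cx <= w and 0 <= cy <= h):
            raise TrackingError("principal point outside image bounds")


@dataclass(frozen=True)
class MarkerObservation:
    """Four ordered marker-corner pixels from one camera, or a miss.

    ``corner_pixels`` is a (4, 2) array, or ``None`` when the marker was
    not detected in this frame.
    """

    corner_pixels: np.ndarray | None
    camera_id: str
    time: float

    def __post_init__(self) -> None:
        if self.camera_id not in ("left", "right"):
            raise TrackingError(f"unknown camera_id {self.camera_id!r}")
        if self.corner_pixels is not None:
            c = np.asarray(self.corner_pixels, dtype=float).reshape(4, 2)
            object.__setattr__(self, "corner_pixels", c)

    @property
    def detected(self) -> bool:
        return self.corner_pixels is not None


@dataclass(frozen=True)
class TrackedSample:
    """One timestamped 6-DOF marker pose in the left-camera frame.

    ``source`` records provenance: ``left`` / ``right`` camera, or
    ``held`` when the pose was copied from the previous frame after a
    dropout.
    """

    time: float
    position: np.ndarray
    orientation: np.ndarray
    source: str = "left"

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        q = np.asarray(self.orientation, dtype=float).reshape(4)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-6:
            raise TrackingError(f"quaternion norm {n} deviates from 1")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "orientation", q / n)
        if self.source not in ("left", "right", "held"):
            raise TrackingError(f"unknown source {self.source!r}")

    def with_time(self, time: float, source: str | None = None) -> "TrackedSample":
        return dataclasses.replace(self, time=time, source=source or self.source)


@dataclass(frozen=True)
class StereoRig:
    """Fixed two-camera rig: intrinsics, right-from-left transform, marker side (cm)."""

    K_l: CameraIntrinsics
    K_r: CameraIntrinsics
    T_rl: RigidTransform
    marker_side: float = 4.0


def transform_point(T: RigidTransform, p) -> np.ndarray:
    """Apply a rigid transform: ``rotation @ p + translation``."""
    return T.apply(p)


def project_to_screen(K: CameraIntrinsics, p_cam) -> np.ndarray:
    """Perspective-project a camera-frame point onto the screen (pixels)."""
    p = np.asarray(p_cam, dtype=float)
    if p.ndim == 1:
        if p[2] <= 0:
            raise BehindCameraError("point behind camera (depth <= 0)")
        h = K.matrix @ p
        return h[:2] / h[2]
    if np.any(p[:, 2] <= 0):
        raise BehindCameraError("point behind camera (depth <= 0)")
    h = p @ K.matrix.T
    return h[:, :2] / h[:, 2:3]


def relative_camera_transform(
    T_ml: RigidTransform, T_mr: RigidTransform
) -> RigidTransform:
    """Right-from-left chain ``T_rl = T_mr⁻¹ ∘ T_ml``.

    ``T_ml`` and ``T_mr`` map left/right camera coordinates into the
    shared marker frame; eliminating the marker frame yields the fixed
    transform taking left-camera points to right-camera points.
    """
    return T_mr.inverse().compose(T_ml)


def marker_corners(side: float) -> np.ndarray:
    """Canonical square-marker corners in the marker z=0 plane (cm).

    Counter-clockwise starting at the top-left corner: (-s/2, +s/2),
    (-s/2, -s/2), (+s/2, -s/2), (+s/2, +s/2).
    """
    s = side / 2.0
    return np.array(
        [[-s, s, 0.0], [-s, -s, 0.0], [s, -s, 0.0], [s, s, 0.0]]
    )


def synthesize_observation(
    K: CameraIntrinsics,
    T_cm: RigidTransform,
    side: float,
    camera_id: str,
    time: float,
    rng: np.random.Generator | None = None,
    pixel_noise: float = 0.0,
) -> MarkerObservation:
    """Project the canonical marker square through K·T_cm into pixels."""
    pix = project_to_screen(K, T_cm.apply(marker_corners(side)))
    if pixel_noise > 0:
        if rng is None:
            rng = np.random.default_rng()
        pix = pix + rng.normal(0.0, pixel_noise, pix.shape)
    return MarkerObservation(pix, camera_id, time)


def _homography_dlt(src_xy: np.ndarray, dst_xy: np.ndarray) -> np.ndarray:
    """Plane-to-image homography from 4 point correspondences (DLT).

    Hartley normalization keeps the 8x9 system well conditioned.
    """

    def normalizer(pts):
        c = pts.mean(axis=0)
        scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - c, axis=1)), 1e-12)
        T = np.array(
            [[scale, 0, -scale * c[0]], [0, scale, -scale * c[1]], [0, 0, 1]]
        )
        return T

    Ts, Td = normalizer(src_xy), normalizer(dst_xy)
    s = np.column_stack([src_xy, np.ones(4)]) @ Ts.T
    d = np.column_stack([dst_xy, np.ones(4)]) @ Td.T

    A = []
    for (x, y, _), (u, v, _) in zip(s, d):
        A.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        A.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    A = np.asarray(A)
    _, sv, Vt = np.linalg.svd(A)
    if sv[-2] < 1e-9 * sv[0]:
        raise PoseEstimationError("pose unrecoverable: degenerate corners")
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    return H / H[2, 2]


def estimate_pose_from_square(
    K: CameraIntrinsics, obs: MarkerObservation, side_length: float
) -> RigidTransform:
    """Recover the camera-from-marker transform from 4 corner pixels.

    A planar homography is fit to the correspondence between the
    canonical marker square and the observed pixels, then decomposed
    against K; the rotation is re-orthonormalized by SVD.  The marker is
    required to lie in front of the camera (positive depth).
    """
    if obs.corner_pixels is None:
        raise PoseEstimationError("observation has no detected corners")
    corners3d = marker_corners(side_length)
    src = corners3d[:, :2]
    # collinearity check: area of the quad must be non-trivial
    v1 = obs.corner_pixels[1] - obs.corner_pixels[0]
    v2 = obs.corner_pixels[2] - obs.corner_pixels[0]
    v3 = obs.corner_pixels[3] - obs.corner_pixels[0]

    def cross2(a, b):
        return a[0] * b[1] - a[1] * b[0]

    if abs(cross2(v1, v2)) < 1e-9 and abs(cross2(v1, v3)) < 1e-9:
        raise PoseEstimationError("pose unrecoverable: collinear corners")

    H = _homography_dlt(src, obs.corner_pixels)
    M = np.linalg.inv(K.matrix) @ H
    n1, n2 = np.linalg.norm(M[:, 0]), np.linalg.norm(M[:, 1])
    if n1 < 1e-12 or n2 < 1e-12:
        raise PoseEstimationError("pose unrecoverable: degenerate homography")
    lam = 2.0 / (n1 + n2)
    if M[2, 2] * lam < 0:  # marker origin must project with positive depth
        lam = -lam
    r1 = lam * M[:, 0]
    r2 = lam * M[:, 1]
    t = lam * M[:, 2]
    R_approx = np.column_stack([r1, r2, np.cross(r1, r2)])
    U, _, Vt = np.linalg.svd(R_approx)
    R = U @ np.diag([1.0, 1.0, np.linalg.det(U @ Vt)]) @ Vt
    return RigidTransform(R, t)


def resolve_marker_pose(
    left: MarkerObservation,
    right: MarkerObservation,
    prev: TrackedSample | None,
    rig: StereoRig,
    side: float | None = None,
) -> TrackedSample:
    """One step of the two-camera tracking cascade.

    Left camera wins when it sees the marker; otherwise the right-camera
    pose is mapped through ``T_rl`` into the left-camera frame; otherwise
    the previous sample is held with an updated timestamp.
    """
    s = rig.marker_side if side is None else side
    if left.detected:
        T_lm = estimate_pose_from_square(rig.K_l, left, s)
        return TrackedSample(
            left.time, T_lm.translation, T_lm.quaternion(), source="left"
        )
    if right.detected:
        T_rm = estimate_pose_from_square(rig.K_r, right, s)
        T_lm = rig.T_rl.inverse().compose(T_rm)
        return TrackedSample(
            right.time, T_lm.translation, T_lm.quaternion(), source="right"
        )
    if prev is not None:
        return prev.with_time(max(left.time, right.time), source="held")
    raise NoPoseAvailableError("no pose available: both cameras missed and no history")
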