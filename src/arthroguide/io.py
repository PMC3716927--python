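"""File formats and run metadata.

Trajectories travel as CSV (`time,x,y,z,qw,qx,qy,qz,source`; seconds and
cm, 6 decimals), curves as JSON, rig and guidance configuration as YAML.
Every artifact written by a run embeds the tool version and a SHA-256
hash of the effective configuration so outputs are traceable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .guidance import GuidanceConfig
from .nurbs import NurbsCurve, NurbsError, RawTrajectory
from .tracking import CameraIntrinsics, RigidTransform, StereoRig, TrackedSample

__all__ = [
    "TrajectoryFormatError",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_curve_json",
    "write_curve_json",
    "read_rig_config",
    "write_rig_config",
    "read_guidance_config",
    "config_hash",
    "run_metadata",
]

TRAJECTORY_COLUMNS = ["time", "x", "y", "z", "qw", "qx", "qy", "qz", "source"]


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file."""


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a configuration mapping (first 12 hex digits)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_metadata(config: dict) -> dict:
    return {"tool": "arthroguide", "version": __version__,
            "config_hash": config_hash(config), "config": config}


def read_trajectory_csv(path) -> RawTrajectory:
    """Read and validate a trajectory CSV.

    Lines starting with '#' are metadata and ignored.  Timestamps must
    strictly increase; quaternions off unit norm by more than 1e-6 are
    renormalized with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {missing}")
    num = df[TRAJECTORY_COLUMNS[:-1]].apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        row = int(num[num.isna().any(axis=1)].index[0])
        raise TrajectoryFormatError(f"{path}: malformed row at data line {row + 2}")

    samples = []
    for row in df.itertuples(index=False):
        q = np.array([row.qw, row.qx, row.qy, row.qz], dtype=float)
        norm = np.linalg.norm(q)
        if abs(norm - 1.0) > 1e-6:
            warnings.warn(
                f"{path}: quaternion norm {norm:.8f} at t={row.time}; renormalized",
                stacklevel=2,
            )
            q = q / norm
        samples.append(
            TrackedSample(float(row.time), [row.x, row.y, row.z], q, str(row.source))
        )
    try:
        return RawTrajectory(tuple(samples))
    except NurbsError as exc:
        raise TrajectoryFormatError(f"{path}: {exc}") from exc


def write_trajectory_csv(path, traj: RawTrajectory, config: dict | None = None) -> None:
    """Write a trajectory CSV with 6-decimal precision and a metadata header."""
    path = Path(path)
    meta = run_metadata(config or {})
    with path.open("w") as fh:
        fh.write(f"# tool=arthroguide version={meta['version']} "
                 f"config_hash={meta['config_hash']}\n")
        fh.write(",".join(TRAJECTORY_COLUMNS) + "\n")
        for s in traj.samples:
            vals = [s.time, *s.position, *s.orientation]
            fh.write(",".join(f"{v:.6f}" for v in vals) + f",{s.source}\n")


def read_curve_json(path) -> NurbsCurve:
    text = Path(path).read_text()
    payload = json.loads(text)
    if "curve" in payload:  # written with metadata envelope
        payload = payload["curve"]
    return NurbsCurve.from_json(json.dumps(payload))


def write_curve_json(path, curve: NurbsCurve, config: dict | None = None) -> None:
    meta = run_metadata(config or {})
    payload = {
        "tool": meta["tool"],
        "version": meta["version"],
        "config_hash": meta["config_hash"],
        "curve": json.loads(curve.to_json()),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def _intrinsics_from_dict(d: dict) -> CameraIntrinsics:
    K = np.asarray(d["matrix"], dtype=float).reshape(3, 3)
    size = tuple(d.get("image_size", (640, 480)))
    return CameraIntrinsics(K, size)


def _transform_from_dict(d: dict) -> RigidTransform:
    return RigidTransform.from_quaternion(d["quaternion_wxyz"], d["translation_cm"])


def read_rig_config(path) -> StereoRig:
    """Stereo rig from YAML: K_l, K_r (row-major 9 numbers + image size),
    marker side length (cm), and T_rl as quaternion + translation."""
    d = yaml.safe_load(Path(path).read_text())
    return StereoRig(
        K_l=_intrinsics_from_dict(d["K_l"]),
        K_r=_intrinsics_from_dict(d["K_r"]),
        T_rl=_transform_from_dict(d["T_rl"]),
        marker_side=float(d.get("marker_side_cm", 4.0)),
    )


def write_rig_config(path, rig: StereoRig) -> None:
    d = {
        "K_l": {"matrix": rig.K_l.matrix.ravel().tolist(),
                "image_size": list(rig.K_l.image_size)},
        "K_r": {"matrix": rig.K_r.matrix.ravel().tolist(),
                "image_size": list(rig.K_r.image_size)},
        "T_rl": {"quaternion_wxyz": rig.T_rl.quaternion().tolist(),
                 "translation_cm": rig.T_rl.translation.tolist()},
        "marker_side_cm": rig.marker_side,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_guidance_config(path) -> GuidanceConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    return GuidanceConfig(**d)
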