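"""Skeleton data model, body-centric coordinate frame, and mirroring.

A skeleton frame is a set of 20 named joint centers in a right-handed world
frame with Z the true vertical and the floor at Z = 0, in meters.  The
body-centric frame used throughout the package has its origin at the
shoulder/hip centroid, Z equal to the world vertical, X the horizontal
component of the hip-plane normal (pointing anteriorly), and Y completing a
right-handed system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd


class JointName(str, Enum):
    """The 20 joint centers reported by consumer depth-camera skeletons."""

    HIP_CENTER = "hip_center"
    SPINE = "spine"
    SHOULDER_CENTER = "shoulder_center"
    HEAD = "head"
    LEFT_SHOULDER = "left_shoulder"
    LEFT_ELBOW = "left_elbow"
    LEFT_WRIST = "left_wrist"
    LEFT_HAND = "left_hand"
    RIGHT_SHOULDER = "right_shoulder"
    RIGHT_ELBOW = "right_elbow"
    RIGHT_WRIST = "right_wrist"
    RIGHT_HAND = "right_hand"
    LEFT_HIP = "left_hip"
    LEFT_KNEE = "left_knee"
    LEFT_ANKLE = "left_ankle"
    LEFT_FOOT = "left_foot"
    RIGHT_HIP = "right_hip"
    RIGHT_KNEE = "right_knee"
    RIGHT_ANKLE = "right_ankle"
    RIGHT_FOOT = "right_foot"


JOINTS: tuple[JointName, ...] = tuple(JointName)
N_JOINTS = len(JOINTS)
JOINT_INDEX: dict[JointName, int] = {j: i for i, j in enumerate(JOINTS)}

#: left<->right swap map used by XZ-plane mirroring (bijective on joints)
MIRROR_SWAP: dict[JointName, JointName] = {}
for _j in JOINTS:
    if _j.value.startswith("left_"):
        MIRROR_SWAP[_j] = JointName("right_" + _j.value[5:])
    elif _j.value.startswith("right_"):
        MIRROR_SWAP[_j] = JointName("left_" + _j.value[6:])
    else:
        MIRROR_SWAP[_j] = _j

#: row permutation implementing the left/right label swap
MIRROR_PERMUTATION = np.array([JOINT_INDEX[MIRROR_SWAP[j]] for j in JOINTS])


class SkeletonError(ValueError):
    """Invalid skeleton input (missing joints, degenerate geometry)."""


class DegenerateBodyFrameError(SkeletonError):
    """The hip triangle is degenerate and no body frame can be defined."""


@dataclass(frozen=True)
class SkeletonFrame:
    """One time-stamped skeleton: 20 joints x 3 coordinates, meters.

    ``xyz`` rows follow the :data:`JOINTS` enumeration order.
    """

    time: float
    xyz: np.ndarray  # (20, 3)

    def __post_init__(self) -> None:
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (N_JOINTS, 3):
            raise SkeletonError(f"expected ({N_JOINTS}, 3) joint array, got {xyz.shape}")
        object.__setattr__(self, "xyz", xyz)

    def position(self, joint: JointName) -> np.ndarray:
        return self.xyz[JOINT_INDEX[joint]]

    def require_finite(self) -> None:
        if not np.isfinite(self.xyz).all():
            raise SkeletonError("skeleton frame contains non-finite coordinates")


@dataclass(frozen=True)
class BodyFrameTransform:
    """Rigid transform from world to body-centric coordinates.

    ``basis`` rows are the body X, Y, Z axes expressed in world coordinates,
    so body coordinates are ``basis @ (p - origin)``.
    """

    origin: np.ndarray  # (3,)
    basis: np.ndarray  # (3, 3), orthonormal, det +1

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.origin) @ self.basis.T

    def apply_frame(self, frame: SkeletonFrame) -> SkeletonFrame:
        return SkeletonFrame(frame.time, self.apply(frame.xyz))


@dataclass
class SkeletonSequence:
    """An ordered sequence of skeleton frames from one recording stream."""

    times: np.ndarray  # (n,)
    data: np.ndarray  # (n, 20, 3)
    nominal_rate: float = 30.0
    subject_id: str = ""
    trial_id: str = ""
    stream: str = "noisy"  # {"noisy", "reference"}

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1:] != (N_JOINTS, 3):
            raise SkeletonError(f"expected (n, {N_JOINTS}, 3) data, got {self.data.shape}")
        if len(self.times) != len(self.data):
            raise SkeletonError("times and data lengths differ")

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self) -> Iterator[SkeletonFrame]:
        for t, xyz in zip(self.times, self.data):
            yield SkeletonFrame(float(t), xyz)

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(float(self.times[i]), self.data[i])

    @property
    def duration(self) -> float:
        """Recording span in seconds, counting one sample interval per frame."""
        return len(self) / self.nominal_rate

    def joint(self, joint: JointName) -> np.ndarray:
        """(n, 3) trajectory of one joint."""
        return self.data[:, JOINT_INDEX[joint], :]

    def slice(self, start: int, stop: int) -> "SkeletonSequence":
        return replace(self, times=self.times[start:stop], data=self.data[start:stop])


# ---------------------------------------------------------------------------
# body-centric frame


def _hip_plane_anterior_x(xyz: np.ndarray) -> np.ndarray:
    """Horizontal unit normal of the hip plane for (..., 20, 3) arrays.

    The sign is *not* resolved here; callers apply the anterior convention.
    Raises on a degenerate hip triangle or a vertical hip-plane normal.
    """
    hc = xyz[..., JOINT_INDEX[JointName.HIP_CENTER], :]
    lh = xyz[..., JOINT_INDEX[JointName.LEFT_HIP], :]
    rh = xyz[..., JOINT_INDEX[JointName.RIGHT_HIP], :]
    normal = np.cross(rh - hc, lh - hc)
    area = 0.5 * np.linalg.norm(normal, axis=-1)
    if np.any(area <= 1e-9):
        raise DegenerateBodyFrameError("hip joints are collinear; body frame undefined")
    horiz = normal.copy()
    horiz[..., 2] = 0.0
    norm = np.linalg.norm(horiz, axis=-1, keepdims=True)
    if np.any(norm <= 1e-12):
        raise DegenerateBodyFrameError("hip-plane normal is vertical; anterior axis undefined")
    return horiz / norm


_TORSO_ROWS = [
    JOINT_INDEX[JointName.LEFT_SHOULDER],
    JOINT_INDEX[JointName.RIGHT_SHOULDER],
    JOINT_INDEX[JointName.LEFT_HIP],
    JOINT_INDEX[JointName.RIGHT_HIP],
]
_WRIST_ROWS = [JOINT_INDEX[JointName.LEFT_WRIST], JOINT_INDEX[JointName.RIGHT_WRIST]]


def to_body_frame(
    frame: SkeletonFrame, prev_x: np.ndarray | None = None
) -> tuple[BodyFrameTransform, SkeletonFrame]:
    """Compute the body-centric frame of ``frame`` and re-express it there.

    Origin: mean of the left/right shoulder and left/right hip joint centers.
    Z: world vertical.  X: horizontal component of the hip-plane normal,
    oriented anteriorly — by continuity with ``prev_x`` when given, otherwise
    so that the mean wrist position has non-negative body X.  Y = Z x X.
    """
    frame.require_finite()
    x = _hip_plane_anterior_x(frame.xyz)
    origin = frame.xyz[_TORSO_ROWS].mean(axis=0)
    if prev_x is not None:
        if float(np.dot(x, prev_x)) < 0.0:
            x = -x
    else:
        wrist_mean = frame.xyz[_WRIST_ROWS].mean(axis=0)
        if float(np.dot(wrist_mean - origin, x)) < 0.0:
            x = -x
    z = np.array([0.0, 0.0, 1.0])
    y = np.cross(z, x)
    basis = np.vstack([x, y, z])
    transform = BodyFrameTransform(origin=origin, basis=basis)
    return transform, transform.apply_frame(frame)


def body_frame_sequence(seq: SkeletonSequence) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized body frames for every frame of a sequence.

    Returns ``(origins, bases)`` with shapes (n, 3) and (n, 3, 3).  The
    anterior sign is propagated frame to frame (temporal continuity), seeded
    on the first frame by the mean-wrist rule of :func:`to_body_frame`.
    """
    xyz = seq.data
    x = _hip_plane_anterior_x(xyz)  # (n, 3)
    origins = xyz[:, _TORSO_ROWS, :].mean(axis=1)
    wrist_mean = xyz[:, _WRIST_ROWS, :].mean(axis=1)
    if len(xyz) and np.dot(wrist_mean[0] - origins[0], x[0]) < 0.0:
        x[0] = -x[0]
    # propagate sign: flip wherever continuity with the previous frame breaks
    flips = np.einsum("ij,ij->i", x[1:], x[:-1]) < 0.0
    sign = np.concatenate([[1.0], np.where(flips, -1.0, 1.0)]).cumprod()
    x = x * sign[:, None]
    z = np.zeros_like(x)
    z[:, 2] = 1.0
    y = np.cross(z, x)
    bases = np.stack([x, y, z], axis=1)  # rows = body axes
    return origins, bases


def sequence_to_body_frame(seq: SkeletonSequence) -> SkeletonSequence:
    """Re-express every frame of ``seq`` in its own body-centric frame."""
    origins, bases = body_frame_sequence(seq)
    body = np.einsum("nab,njb->nja", bases, seq.data - origins[:, None, :])
    return replace(seq, data=body)


def mirror_xz(seq: SkeletonSequence) -> SkeletonSequence:
    """Mirror a body-frame sequence across the XZ plane.

    Y coordinates are negated and left/right joint labels swapped; the
    operation is an involution and preserves all inter-joint distances.  It
    is meaningful only for sequences already expressed in the body frame,
    where Y is the left-right axis.
    """
    mirrored = seq.data[:, MIRROR_PERMUTATION, :].copy()
    mirrored[:, :, 1] = -mirrored[:, :, 1]
    return replace(seq, data=mirrored)


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """Problems found in a skeleton sequence; empty lists mean a clean pass."""

    nonfinite_frames: list[int] = field(default_factory=list)
    monotonicity_violations: list[int] = field(default_factory=list)
    rate_deviation_hz: float = 0.0
    rate_flagged: bool = False

    @property
    def ok(self) -> bool:
        return not (self.nonfinite_frames or self.monotonicity_violations or self.rate_flagged)

    def problems(self) -> list[str]:
        out = []
        if self.nonfinite_frames:
            out.append(f"non-finite coordinates in frames {self.nonfinite_frames[:10]}")
        if self.monotonicity_violations:
            out.append(f"non-increasing timestamps at indices {self.monotonicity_violations[:10]}")
        if self.rate_flagged:
            out.append(f"observed rate deviates from nominal by {self.rate_deviation_hz:.2f} Hz")
        return out


def validate_sequence(seq: SkeletonSequence, rate_tolerance_hz: float = 2.0) -> ValidationReport:
    """Screen a sequence for non-finite values, timestamp order, and rate."""
    report = ValidationReport()
    bad = ~np.isfinite(seq.data).all(axis=(1, 2))
    report.nonfinite_frames = list(np.nonzero(bad)[0])
    dt = np.diff(seq.times)
    report.monotonicity_violations = list(np.nonzero(dt <= 0)[0] + 1)
    if len(seq) >= 2 and not report.monotonicity_violations:
        observed = 1.0 / np.median(dt)
        report.rate_deviation_hz = abs(observed - seq.nominal_rate)
        report.rate_flagged = report.rate_deviation_hz > rate_tolerance_hz
    return report


# ---------------------------------------------------------------------------
# I/O: CSV with one row per frame plus a JSON sidecar for metadata

CSV_COLUMNS = ["time_s"] + [f"{j.value}_{ax}" for j in JOINTS for ax in "xyz"]


def _convert_y_up(data: np.ndarray) -> np.ndarray:
    """Map a right-handed Y-up convention onto the package's Z-up world."""
    out = np.empty_like(data)
    out[..., 0] = data[..., 0]
    out[..., 1] = -data[..., 2]
    out[..., 2] = data[..., 1]
    return out


def write_sequence(seq: SkeletonSequence, csv_path: str | Path) -> None:
    """Write a sequence as CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    flat = seq.data.reshape(len(seq), -1)
    df = pd.DataFrame(np.column_stack([seq.times, flat]), columns=CSV_COLUMNS)
    df.to_csv(csv_path, index=False)
    meta = {
        "subject_id": seq.subject_id,
        "trial_id": seq.trial_id,
        "stream": seq.stream,
        "nominal_rate_hz": seq.nominal_rate,
        "source_convention": "z_up",
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_sequence(csv_path: str | Path) -> SkeletonSequence:
    """Read a sequence written by :func:`write_sequence` (or hand-made CSV).

    The JSON sidecar is optional; ``source_convention: y_up`` triggers axis
    conversion into the package's Z-up world frame.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SkeletonError(f"skeleton CSV missing columns: {missing[:5]}")
    times = df["time_s"].to_numpy(float)
    data = df[CSV_COLUMNS[1:]].to_numpy(float).reshape(len(df), N_JOINTS, 3)
    meta_path = csv_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if meta.get("source_convention", "z_up") == "y_up":
        data = _convert_y_up(data)
    return SkeletonSequence(
        times=times,
        data=data,
        nominal_rate=float(meta.get("nominal_rate_hz", 30.0)),
        subject_id=str(meta.get("subject_id", "")),
        trial_id=str(meta.get("trial_id", "")),
        stream=str(meta.get("stream", "noisy")),
    )
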