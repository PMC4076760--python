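"""Shared fixtures: hand-built poses and synthetic sequences."""

from __future__ import annotations

import numpy as np
import pytest

from ergolift.skeleton import (
    JOINT_INDEX,
    N_JOINTS,
    JointName,
    SkeletonFrame,
    SkeletonSequence,
)

#: explicit standing pose facing world +X (meters, Z-up, floor at Z = 0)
BASE_POSE: dict[JointName, tuple[float, float, float]] = {
    JointName.HIP_CENTER: (0.00, 0.00, 0.95),
    JointName.SPINE: (0.02, 0.00, 1.15),
    JointName.SHOULDER_CENTER: (0.02, 0.00, 1.40),
    JointName.HEAD: (0.03, 0.00, 1.60),
    JointName.LEFT_SHOULDER: (0.02, 0.18, 1.40),
    JointName.LEFT_ELBOW: (0.15, 0.20, 1.20),
    JointName.LEFT_WRIST: (0.30, 0.15, 1.05),
    JointName.LEFT_HAND: (0.35, 0.15, 1.02),
    JointName.RIGHT_SHOULDER: (0.02, -0.18, 1.40),
    JointName.RIGHT_ELBOW: (0.15, -0.20, 1.20),
    JointName.RIGHT_WRIST: (0.30, -0.15, 1.05),
    JointName.RIGHT_HAND: (0.35, -0.15, 1.02),
    JointName.LEFT_HIP: (-0.02, 0.10, 0.93),
    JointName.LEFT_KNEE: (0.03, 0.11, 0.50),
    JointName.LEFT_ANKLE: (0.00, 0.10, 0.08),
    JointName.LEFT_FOOT: (0.12, 0.10, 0.02),
    JointName.RIGHT_HIP: (-0.02, -0.10, 0.93),
    JointName.RIGHT_KNEE: (0.03, -0.11, 0.50),
    JointName.RIGHT_ANKLE: (0.00, -0.10, 0.08),
    JointName.RIGHT_FOOT: (0.12, -0.10, 0.02),
}


def pose_array(overrides: dict[JointName, tuple] | None = None) -> np.ndarray:
    xyz = np.zeros((N_JOINTS, 3))
    for joint, pos in BASE_POSE.items():
        xyz[JOINT_INDEX[joint]] = pos
    for joint, pos in (overrides or {}).items():
        xyz[JOINT_INDEX[joint]] = pos
    return xyz


def make_frame(time: float = 0.0, overrides: dict[JointName, tuple] | None = None) -> SkeletonFrame:
    return SkeletonFrame(time=time, xyz=pose_array(overrides))


def make_sequence(
    n: int = 300, rate: float = 30.0, wrist_z: np.ndarray | None = None
) -> SkeletonSequence:
    """Tile the base pose; optionally drive both wrist/hand heights."""
    data = np.tile(pose_array(), (n, 1, 1))
    if wrist_z is not None:
        for joint in (
            JointName.LEFT_WRIST,
            JointName.RIGHT_WRIST,
            JointName.LEFT_HAND,
            JointName.RIGHT_HAND,
        ):
            data[:, JOINT_INDEX[joint], 2] = wrist_z
    return SkeletonSequence(times=np.arange(n) / rate, data=data, nominal_rate=rate)


def yaw_translate(xyz: np.ndarray, yaw_deg: float, shift_xy=(0.0, 0.0)) -> np.ndarray:
    """World yaw rotation about Z plus a horizontal translation."""
    c, s = np.cos(np.radians(yaw_deg)), np.sin(np.radians(yaw_deg))
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return xyz @ rot.T + np.array([shift_xy[0], shift_xy[1], 0.0])


def random_frames(rng: np.random.Generator, n: int = 50) -> list[SkeletonFrame]:
    """Diverse valid poses: builder poses under random yaw and translation."""
    from ergolift.synthetic import _build_sequence

    frames = []
    for _ in range(n):
        r = rng.uniform(0.20, 0.60)
        az = rng.uniform(-80.0, 80.0)
        v = rng.uniform(5.0, 150.0)
        scale = rng.uniform(0.9, 1.1)
        seq = _build_sequence(
            np.array([0.0]), np.array([r]), np.array([az]), np.array([v]), scale, 30.0
        )
        xyz = yaw_translate(
            seq.data[0], rng.uniform(-180, 180), rng.uniform(-2, 2, size=2)
        )
        frames.append(SkeletonFrame(time=0.0, xyz=xyz))
    return frames


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def base_frame() -> SkeletonFrame:
    return make_frame()
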