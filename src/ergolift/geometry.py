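"""Per-frame geometric extraction of lifting-equation parameters.

H is the horizontal distance (cm) between the ankle midpoint and the floor
projection of the hand midpoint; V is the hand midpoint's height above the
floor (cm); A is the unsigned angle (degrees) between the asymmetry line
(ankle midpoint to hand projection) and the mid-sagittal (anterior) line;
D is the vertical hand travel (cm) between lift origin and destination.

Input skeletons are in meters in the world frame; results are cm / degrees.
The hand anchor defaults to the wrist joints, which consumer skeleton
algorithms track more stably than the hand tips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .skeleton import (
    JOINT_INDEX,
    JointName,
    SkeletonFrame,
    SkeletonSequence,
    body_frame_sequence,
    to_body_frame,
)

_ANKLE_ROWS = [JOINT_INDEX[JointName.LEFT_ANKLE], JOINT_INDEX[JointName.RIGHT_ANKLE]]

_HAND_ANCHORS = {
    "wrist": [JOINT_INDEX[JointName.LEFT_WRIST], JOINT_INDEX[JointName.RIGHT_WRIST]],
    "hand": [JOINT_INDEX[JointName.LEFT_HAND], JOINT_INDEX[JointName.RIGHT_HAND]],
}


@dataclass(frozen=True)
class FrameParameters:
    """Instantaneous lifting-equation geometry at one frame."""

    H: float  # cm
    V: float  # cm
    A: float  # degrees, unsigned in [0, 180]
    time: float = 0.0
    asymmetry_defined: bool = True


def _anchor_rows(hand_anchor: str) -> list[int]:
    try:
        return _HAND_ANCHORS[hand_anchor]
    except KeyError:
        raise ValueError(f"unknown hand anchor {hand_anchor!r}; use 'wrist' or 'hand'") from None


def hand_midpoint(frame: SkeletonFrame, hand_anchor: str = "wrist") -> np.ndarray:
    frame.require_finite()
    return frame.xyz[_anchor_rows(hand_anchor)].mean(axis=0)


def ankle_midpoint(frame: SkeletonFrame) -> np.ndarray:
    frame.require_finite()
    return frame.xyz[_ANKLE_ROWS].mean(axis=0)


def horizontal_location(frame: SkeletonFrame, hand_anchor: str = "wrist") -> float:
    """H: planar ankle-midpoint to hand-projection distance, in cm."""
    delta = hand_midpoint(frame, hand_anchor)[:2] - ankle_midpoint(frame)[:2]
    return float(np.hypot(*delta) * 100.0)


def vertical_location(frame: SkeletonFrame, hand_anchor: str = "wrist") -> float:
    """V: hand midpoint height above the floor, in cm.

    Sensor noise can push V slightly negative; the raw value is preserved
    here and clamped only inside the vertical multiplier.
    """
    return float(hand_midpoint(frame, hand_anchor)[2] * 100.0)


def asymmetry_angle(
    frame: SkeletonFrame, hand_anchor: str = "wrist", return_defined: bool = False
):
    """A: unsigned floor-plane angle between asymmetry line and sagittal line.

    When the hands project onto the ankle midpoint (H = 0) the angle is
    undefined; 0 is returned, flagged when ``return_defined`` is set.
    """
    transform, _ = to_body_frame(frame)
    sagittal = transform.basis[0, :2]  # anterior body X, already horizontal
    radial = hand_midpoint(frame, hand_anchor)[:2] - ankle_midpoint(frame)[:2]
    r = np.linalg.norm(radial)
    if r < 1e-9:
        return (0.0, False) if return_defined else 0.0
    cosang = np.clip(np.dot(radial / r, sagittal / np.linalg.norm(sagittal)), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    return (angle, True) if return_defined else angle


def travel_distance(v_origin: float, v_destination: float) -> float:
    """D: absolute vertical hand travel between lift origin and destination, cm."""
    return float(abs(v_destination - v_origin))


def frame_parameters(frame: SkeletonFrame, hand_anchor: str = "wrist") -> FrameParameters:
    a, defined = asymmetry_angle(frame, hand_anchor, return_defined=True)
    return FrameParameters(
        H=horizontal_location(frame, hand_anchor),
        V=vertical_location(frame, hand_anchor),
        A=a,
        time=frame.time,
        asymmetry_defined=defined,
    )


def sequence_parameters(seq: SkeletonSequence, hand_anchor: str = "wrist") -> pd.DataFrame:
    """Vectorized per-frame H, V, A for a whole sequence.

    Returns a DataFrame indexed by frame with columns ``H`` (cm), ``V``
    (cm), ``A`` (deg), and ``time`` (s).
    """
    rows = _anchor_rows(hand_anchor)
    hands = seq.data[:, rows, :].mean(axis=1)
    ankles = seq.data[:, _ANKLE_ROWS, :].mean(axis=1)
    radial = hands[:, :2] - ankles[:, :2]
    r = np.linalg.norm(radial, axis=1)
    _, bases = body_frame_sequence(seq)
    sagittal = bases[:, 0, :2]
    sagittal = sagittal / np.linalg.norm(sagittal, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", radial, sagittal) / np.where(r > 1e-9, r, np.nan)
    a = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    a = np.where(r > 1e-9, a, 0.0)
    return pd.DataFrame(
        {"H": r * 100.0, "V": hands[:, 2] * 100.0, "A": a, "time": seq.times}
    )
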