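"""Synthetic paired lifting recordings with programmed task parameters.

The generator stands in for laboratory recordings: a reference stream plays
the role of optical motion capture, and a corrupted copy emulates a
depth-camera skeleton, including the systematic *underestimation* of
hand-ankle separation and hand height that depth-camera skeletons show,
a smooth pose-dependent bias field, white marker noise, and sparse gross
outliers.

Kinematics are deliberately simple: an articulated 20-joint chain with
fixed segment lengths scaled by an anthropometric factor, whose hand
midpoint follows a prescribed (H, A, V(t)) trajectory.  At every lift
origin the geometric parameters equal the programmed ones exactly, which is
what makes the generator usable as its own ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .skeleton import (
    JOINT_INDEX,
    N_JOINTS,
    JointName,
    SkeletonSequence,
    body_frame_sequence,
)

_J = JOINT_INDEX


class SyntheticSpecError(ValueError):
    """The requested trial is anatomically impossible for the skeleton."""


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Programmed task parameters of one synthetic trial."""

    true_H: float = 50.0  # cm, horizontal hand-ankle distance at lift origin
    true_V_origin: float = 10.0  # cm, hand height at lift origin
    true_V_destination: float = 80.0  # cm, hand height at destination
    true_A: float = 0.0  # degrees, asymmetry angle (|A| <= 85)
    frequency: float = 10.0  # lifts/min
    duration_s: float = 60.0
    subject_scale: float = 1.0  # anthropometric scale factor
    motion_kind: str = "lift"  # {lift, walk, arm, random}
    rate_hz: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise SyntheticSpecError("duration must be positive")
        if self.motion_kind not in ("lift", "walk", "arm", "random"):
            raise SyntheticSpecError(f"unknown motion kind {self.motion_kind!r}")
        if self.motion_kind == "lift":
            if self.frequency <= 0:
                raise SyntheticSpecError("lift trials need a positive frequency")
            if self.true_H > 85.0 * self.subject_scale:
                raise SyntheticSpecError(
                    f"H = {self.true_H} cm exceeds the arm reach of a "
                    f"scale-{self.subject_scale} skeleton"
                )
            if abs(self.true_A) > 85.0:
                raise SyntheticSpecError("|A| above 85 degrees is outside the generator's range")
            if not -5.0 <= self.true_V_origin <= 180.0 or not -5.0 <= self.true_V_destination <= 180.0:
                raise SyntheticSpecError("hand heights must lie in [-5, 180] cm")


@dataclass(frozen=True)
class NoiseSpec:
    """Corruption model for the emulated depth-camera stream.

    ``bias_sign`` is the fractional systematic shrinkage of the hand-ankle
    horizontal separation and of the hand height: 0.10 means the noisy
    stream underestimates both by 10%, so the parameter errors
    delta = reference - noisy come out positive.
    """

    white_sigma_m: float = 0.01
    bias_amplitude_m: float = 0.03
    bias_sign: float = 0.10
    outlier_rate: float = 0.01
    outlier_magnitude_m: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must lie in [0, 1)")
        for name in ("white_sigma_m", "bias_amplitude_m", "bias_sign", "outlier_magnitude_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# articulated-chain builder


def _build_sequence(
    times: np.ndarray,
    r_m: np.ndarray,
    azimuth_deg: np.ndarray,
    v_cm: np.ndarray,
    scale: float,
    rate_hz: float,
    drift_m: np.ndarray | None = None,
) -> SkeletonSequence:
    """Pose a 20-joint skeleton so the wrist midpoint tracks (r, azimuth, V).

    The body faces world +X; ``azimuth_deg`` is the signed floor-plane angle
    of the hand direction relative to it, so the unsigned asymmetry angle of
    the built frames equals ``|azimuth_deg|``.  ``drift_m`` optionally
    translates the whole skeleton (e.g. walking).
    """
    n = len(times)
    s = scale
    az = np.radians(azimuth_deg)
    u = np.stack([np.cos(az), np.sin(az), np.zeros(n)], axis=1)  # radial
    v_lat = np.stack([-np.sin(az), np.cos(az), np.zeros(n)], axis=1)  # lateral
    z_hat = np.array([0.0, 0.0, 1.0])

    hand_mid = r_m[:, None] * u
    hand_mid[:, 2] = v_cm / 100.0

    xyz = np.zeros((n, N_JOINTS, 3))

    def put(joint: JointName, value: np.ndarray) -> None:
        xyz[:, _J[joint], :] = value

    # planted feet; the ankle midpoint sits exactly above the world origin
    ankle_l = np.tile([0.0, 0.12 * s, 0.08 * s], (n, 1))
    ankle_r = np.tile([0.0, -0.12 * s, 0.08 * s], (n, 1))
    put(JointName.LEFT_ANKLE, ankle_l)
    put(JointName.RIGHT_ANKLE, ankle_r)
    put(JointName.LEFT_FOOT, ankle_l + [0.15 * s, 0.0, -0.06 * s])
    put(JointName.RIGHT_FOOT, ankle_r + [0.15 * s, 0.0, -0.06 * s])

    # pelvis crouches as the hands go low
    z_hip = s * (0.45 + 0.003 * np.clip(v_cm, 0.0, 150.0))
    hip_c = np.zeros((n, 3))
    hip_c[:, 2] = z_hip
    put(JointName.HIP_CENTER, hip_c)
    # lateral hips slightly posterior and below, keeping the hip triangle
    # non-degenerate with an anterior (+X) plane normal
    put(JointName.LEFT_HIP, hip_c + [-0.02 * s, 0.10 * s, -0.02 * s])
    put(JointName.RIGHT_HIP, hip_c + [-0.02 * s, -0.10 * s, -0.02 * s])

    knee_fwd = 0.05 * s + 0.15 * (s - z_hip)
    for side, ankle in ((JointName.LEFT_KNEE, ankle_l), (JointName.RIGHT_KNEE, ankle_r)):
        knee = 0.5 * (ankle + hip_c)
        knee[:, 0] += knee_fwd
        knee[:, 1] = ankle[:, 1] * 0.95
        put(side, knee)

    # torso leans toward the hands as they go low
    lean = np.radians(45.0) * np.clip(1.0 - v_cm / 120.0, 0.0, 1.0)
    torso_dir = np.sin(lean)[:, None] * u + np.cos(lean)[:, None] * z_hat
    shoulder_c = hip_c + 0.45 * s * torso_dir
    put(JointName.SHOULDER_CENTER, shoulder_c)
    put(JointName.SPINE, hip_c + 0.225 * s * torso_dir)
    put(JointName.HEAD, shoulder_c + 0.20 * s * torso_dir)
    put(JointName.LEFT_SHOULDER, shoulder_c + 0.18 * s * v_lat)
    put(JointName.RIGHT_SHOULDER, shoulder_c - 0.18 * s * v_lat)

    wrist_l = hand_mid + 0.10 * s * v_lat
    wrist_r = hand_mid - 0.10 * s * v_lat
    put(JointName.LEFT_WRIST, wrist_l)
    put(JointName.RIGHT_WRIST, wrist_r)
    put(JointName.LEFT_HAND, wrist_l + 0.08 * s * u)
    put(JointName.RIGHT_HAND, wrist_r + 0.08 * s * u)
    put(
        JointName.LEFT_ELBOW,
        0.5 * (xyz[:, _J[JointName.LEFT_SHOULDER]] + wrist_l) + [0.0, 0.05 * s, -0.03 * s],
    )
    put(
        JointName.RIGHT_ELBOW,
        0.5 * (xyz[:, _J[JointName.RIGHT_SHOULDER]] + wrist_r) + [0.0, -0.05 * s, -0.03 * s],
    )

    if drift_m is not None:
        xyz += drift_m[:, None, :]
    return SkeletonSequence(times=times, data=xyz, nominal_rate=rate_hz, stream="reference")


def _smooth_noise(rng: np.random.Generator, n: int, rate: float, cutoff_hz: float = 0.3) -> np.ndarray:
    """Unit-variance smooth random walkway for the 'random' motion kind."""
    white = rng.standard_normal(n + int(4 * rate))
    sos = sps.butter(2, cutoff_hz, btype="low", fs=rate, output="sos")
    smooth = sps.sosfiltfilt(sos, white)[int(2 * rate): int(2 * rate) + n]
    std = smooth.std()
    return smooth / std if std > 0 else smooth


def generate_lift_trial(spec: SyntheticTrialSpec) -> SkeletonSequence:
    """Reference-stream skeleton sequence for one synthetic trial.

    For ``motion_kind='lift'`` the hand midpoint cycles between the
    programmed origin and destination heights at the programmed frequency,
    starting at the origin, so every cycle origin reproduces (H, V, A)
    exactly; the walk/arm/random kinds are pose-space distractors used to
    broaden error-model training data.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate_hz))
    if n < 2:
        raise SyntheticSpecError("trial too short")
    times = np.arange(n) / spec.rate_hz
    s = spec.subject_scale

    if spec.motion_kind == "lift":
        f_hz = spec.frequency / 60.0
        v = spec.true_V_origin + (spec.true_V_destination - spec.true_V_origin) * (
            1.0 - np.cos(2.0 * np.pi * f_hz * times)
        ) / 2.0
        r = np.full(n, spec.true_H / 100.0)
        az = np.full(n, spec.true_A)
        seq = _build_sequence(times, r, az, v, s, spec.rate_hz)
    elif spec.motion_kind == "walk":
        # slightly aperiodic gait (humans are not metronomes), which also
        # keeps the wrist-height autocorrelation unambiguous for alignment
        v = 70.0 * s + 7.0 * np.sin(2.0 * np.pi * 0.8 * times) + 3.0 * np.sin(
            2.0 * np.pi * 0.29 * times + 1.2
        )
        r = (0.25 + 0.05 * np.sin(2.0 * np.pi * 0.8 * times + 1.0)) * s
        az = 15.0 * np.sin(2.0 * np.pi * 0.4 * times)
        drift = np.zeros((n, 3))
        drift[:, 0] = 0.4 * times
        seq = _build_sequence(times, r, az, v, s, spec.rate_hz, drift_m=drift)
    elif spec.motion_kind == "arm":
        v = 90.0 * s + 35.0 * np.sin(2.0 * np.pi * 0.25 * times) + 12.0 * np.sin(
            2.0 * np.pi * 0.113 * times + 0.5
        )
        r = np.full(n, 0.35 * s)
        az = 55.0 * np.sin(2.0 * np.pi * 0.1 * times)
        seq = _build_sequence(times, r, az, v, s, spec.rate_hz)
    else:  # random: smooth seeded wandering, soft-limited to stay in reach
        r = (0.40 + 0.13 * np.tanh(_smooth_noise(rng, n, spec.rate_hz) / 1.2)) * s
        az = 70.0 * np.tanh(_smooth_noise(rng, n, spec.rate_hz) / 1.5)
        v = (80.0 + 50.0 * np.tanh(_smooth_noise(rng, n, spec.rate_hz) / 1.5)) * s
        seq = _build_sequence(times, r, az, v, s, spec.rate_hz)
    return replace(seq, trial_id=f"{spec.motion_kind}-{spec.seed}")


# ---------------------------------------------------------------------------
# depth-camera corruption

_HAND_JOINT_ROWS = [
    _J[JointName.LEFT_WRIST],
    _J[JointName.RIGHT_WRIST],
    _J[JointName.LEFT_HAND],
    _J[JointName.RIGHT_HAND],
]
_ANKLE_ROWS = [_J[JointName.LEFT_ANKLE], _J[JointName.RIGHT_ANKLE]]

#: size of the pose-feature vector driving the bias field: [1, hand-mid
#: body x, y, z] — a low-order polynomial of body-frame coordinates
_N_BIAS_FEATURES = 4


def draw_bias_field(rng: np.random.Generator, symmetric: bool = False) -> np.ndarray:
    """Random bias-field coefficients, one 3x4 matrix per joint.

    With ``symmetric`` the field is made mirror-symmetric: the displacement
    of the mirrored joint at the mirrored pose is the mirror of the
    original displacement.  A depth sensor's pose-dependent error has no
    intrinsic handedness — left/right asymmetries enter through data
    collection — so the device-level (shared) field is symmetric while
    per-subject perturbations need not be.
    """
    from .skeleton import MIRROR_PERMUTATION

    w = rng.standard_normal((N_JOINTS, 3, _N_BIAS_FEATURES)) / np.sqrt(_N_BIAS_FEATURES)
    if symmetric:
        axis_sign = np.array([1.0, -1.0, 1.0])  # mirrored bias negates body Y
        feat_sign = np.array([1.0, 1.0, -1.0, 1.0])  # pose feature cy negates
        w = 0.5 * (
            w
            + axis_sign[None, :, None] * feat_sign[None, None, :] * w[MIRROR_PERMUTATION]
        )
    return w


def corrupt_to_kinect(
    seq: SkeletonSequence,
    noise: NoiseSpec,
    seed: int = 0,
    field_coeffs: np.ndarray | None = None,
) -> SkeletonSequence:
    """Emulated depth-camera stream for a reference sequence.

    Applies, in order: (i) systematic shrinkage of the hand-ankle horizontal
    separation and of the hand height by ``noise.bias_sign``; (ii) a smooth
    pose-dependent bias field — per-joint displacements that are linear in
    the body-frame hand-midpoint position, with coefficients drawn from
    ``seed`` unless supplied; (iii) white Gaussian noise; (iv) sparse gross
    outliers.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    if field_coeffs is None:
        field_coeffs = draw_bias_field(rng)
    xyz = seq.data.copy()
    n = len(xyz)

    # (i) systematic underestimation of hand separation and height
    if noise.bias_sign > 0:
        ankle_xy = xyz[:, _ANKLE_ROWS, :2].mean(axis=1, keepdims=True)
        hands = xyz[:, _HAND_JOINT_ROWS, :]
        hands[:, :, :2] = ankle_xy + (1.0 - noise.bias_sign) * (hands[:, :, :2] - ankle_xy)
        hands[:, :, 2] *= 1.0 - noise.bias_sign
        xyz[:, _HAND_JOINT_ROWS, :] = hands

    # (ii) smooth pose-dependent bias field
    if noise.bias_amplitude_m > 0:
        origins, bases = body_frame_sequence(seq)
        hand_mid = seq.data[:, _HAND_JOINT_ROWS[:2], :].mean(axis=1)
        hand_body = np.einsum("nab,nb->na", bases, hand_mid - origins)
        phi = np.column_stack([np.ones(n), hand_body])  # (n, 4)
        bias_body = np.einsum("jkf,nf->njk", field_coeffs, phi)  # (n, 20, 3)
        bias_world = np.einsum("nba,njb->nja", bases, bias_body)
        xyz += noise.bias_amplitude_m * bias_world

    # (iii) white sensor noise
    if noise.white_sigma_m > 0:
        xyz += rng.normal(0.0, noise.white_sigma_m, size=xyz.shape)

    # (iv) sparse gross outliers: one displaced joint per affected frame
    if noise.outlier_rate > 0 and noise.outlier_magnitude_m > 0:
        hit = rng.random(n) < noise.outlier_rate
        idx = np.nonzero(hit)[0]
        joints = rng.integers(0, N_JOINTS, size=len(idx))
        directions = rng.normal(size=(len(idx), 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        xyz[idx, joints, :] += noise.outlier_magnitude_m * directions

    return replace(seq, data=xyz, stream="noisy")


def default_trial_specs(duration_s: float = 30.0, rate_hz: float = 30.0) -> list[SyntheticTrialSpec]:
    """One trial of each motion kind, mirroring a laboratory session."""
    return [
        SyntheticTrialSpec(
            true_H=50.0, true_V_origin=10.0, true_V_destination=80.0, true_A=20.0,
            frequency=10.0, duration_s=duration_s, rate_hz=rate_hz, motion_kind="lift",
        ),
        SyntheticTrialSpec(duration_s=duration_s, rate_hz=rate_hz, motion_kind="walk"),
        SyntheticTrialSpec(duration_s=duration_s, rate_hz=rate_hz, motion_kind="arm"),
        SyntheticTrialSpec(duration_s=duration_s, rate_hz=rate_hz, motion_kind="random"),
    ]


def generate_paired_dataset(
    n_subjects: int = 6,
    trial_specs: list[SyntheticTrialSpec] | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    mirror: bool = True,
    subject_bias_scale: float = 0.25,
):
    """Paired-corpus generator: per-subject trials, corruption, screening.

    Each subject gets a distinct anthropometric scale and a bias field that
    is the shared dataset-level field plus a smaller subject-specific
    perturbation (``subject_bias_scale``), so the pose-dependent error
    structure is mostly common across subjects and learnable by
    leave-one-subject-out models.

    Returns a :class:`~ergolift.correction.DeltaDataset` of per-frame error
    samples grouped by subject, mirror-augmented when ``mirror`` is set.
    """
    from .correction import DeltaDataset, build_delta_dataset
    from .signal_prep import PrepConfig, preprocess_pair

    if n_subjects < 2:
        raise ValueError("need at least two subjects for leave-one-subject-out use")
    noise = noise or NoiseSpec()
    trial_specs = trial_specs or default_trial_specs()
    master = np.random.default_rng(seed)
    shared_field = draw_bias_field(master, symmetric=True)
    prep = PrepConfig()

    parts = []
    for s in range(n_subjects):
        sub_rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        scale = 1.0 + 0.1 * float(sub_rng.uniform(-1.0, 1.0))
        coeffs = shared_field + subject_bias_scale * draw_bias_field(sub_rng)
        subject_id = f"S{s + 1}"
        for t, base_spec in enumerate(trial_specs):
            spec = replace(
                base_spec, subject_scale=scale, seed=int(sub_rng.integers(0, 2**31 - 1))
            )
            reference = generate_lift_trial(spec)
            reference = replace(
                reference, subject_id=subject_id, trial_id=f"{subject_id}-{spec.motion_kind}-{t}"
            )
            noisy = corrupt_to_kinect(
                reference, noise, seed=int(sub_rng.integers(0, 2**31 - 1)), field_coeffs=coeffs
            )
            pairs = preprocess_pair(noisy, reference, prep)
            parts.append(build_delta_dataset(pairs, subject_id=subject_id, mirror=mirror))
    return DeltaDataset.concat(parts)
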