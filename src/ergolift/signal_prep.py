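"""Resampling, filtering, stream alignment, and outlier screening.

The preprocessing convention for paired recordings is fixed: low-pass
Butterworth on both streams, Savitzky-Golay smoothing on the noisy stream
only, resampling to a uniform grid, then cross-correlation alignment on the
right-wrist vertical coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .skeleton import JointName, SkeletonFrame, SkeletonSequence


class SignalPrepError(ValueError):
    """Invalid filtering/alignment input."""


@dataclass
class Channel:
    """A single scalar time series at a fixed sampling rate."""

    values: np.ndarray
    rate: float
    label: tuple[str, str] = ("", "")  # (joint, axis)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise SignalPrepError("channel rate must be positive")


@dataclass(frozen=True)
class PairedFrame:
    """Time-aligned noisy (K) and reference (Q) skeleton frames."""

    k_frame: SkeletonFrame
    q_frame: SkeletonFrame

    @property
    def time(self) -> float:
        return self.k_frame.time


@dataclass
class PrepConfig:
    """Preprocessing defaults; keys mirror the package configuration file."""

    filter_cutoff_hz: float = 7.0
    filter_order: int = 4
    filter_zero_phase: bool = False
    savgol_window: int = 33
    savgol_degree: int = 3
    resample_rate_hz: float = 30.0
    outlier_threshold_m: float = 0.30


def resample_uniform(seq: SkeletonSequence, rate: float = 30.0) -> SkeletonSequence:
    """Linearly interpolate a sequence onto a uniform time grid.

    The grid starts at the first timestamp and covers the recorded span at
    the requested rate.
    """
    if rate <= 0:
        raise SignalPrepError("target rate must be positive")
    if len(seq) < 2:
        raise SignalPrepError("resampling needs at least two frames")
    t0, t1 = float(seq.times[0]), float(seq.times[-1])
    n = int(np.floor((t1 - t0) * rate)) + 1
    grid = t0 + np.arange(n) / rate
    flat = seq.data.reshape(len(seq), -1)
    out = np.empty((n, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(grid, seq.times, flat[:, c])
    return replace(seq, times=grid, data=out.reshape(n, *seq.data.shape[1:]), nominal_rate=rate)


def _butter_sos(cutoff: float, rate: float, order: int):
    if cutoff >= rate / 2:
        raise SignalPrepError(f"cutoff {cutoff} Hz must be below Nyquist {rate / 2} Hz")
    return signal.butter(order, cutoff, btype="low", fs=rate, output="sos")


def butterworth_lowpass(
    ch: Channel, cutoff: float = 7.0, order: int = 4, zero_phase: bool = False
) -> Channel:
    """Recursive low-pass Butterworth filter on one channel.

    The default is a causal single pass; ``zero_phase`` switches to
    forward-backward filtering for users who prefer no group delay.
    """
    sos = _butter_sos(cutoff, ch.rate, order)
    if zero_phase:
        values = signal.sosfiltfilt(sos, ch.values)
    else:
        # start the recursion from the initial value to soften the transient
        zi = signal.sosfilt_zi(sos) * ch.values[0]
        values, _ = signal.sosfilt(sos, ch.values, zi=zi)
    return Channel(values=values, rate=ch.rate, label=ch.label)


def savgol_smooth(ch: Channel, degree: int = 3, window: int = 33) -> Channel:
    """Savitzky-Golay least-squares polynomial smoothing."""
    if window % 2 == 0 or window <= degree:
        raise SignalPrepError("window must be odd and larger than the polynomial degree")
    values = signal.savgol_filter(ch.values, window_length=window, polyorder=degree)
    return Channel(values=values, rate=ch.rate, label=ch.label)


def filter_sequence(seq: SkeletonSequence, config: PrepConfig | None = None) -> SkeletonSequence:
    """Apply the Butterworth stage to all 60 coordinate channels."""
    config = config or PrepConfig()
    sos = _butter_sos(config.filter_cutoff_hz, seq.nominal_rate, config.filter_order)
    flat = seq.data.reshape(len(seq), -1)
    if config.filter_zero_phase:
        out = signal.sosfiltfilt(sos, flat, axis=0)
    else:
        zi = signal.sosfilt_zi(sos)[:, :, None] * flat[0][None, None, :]
        out, _ = signal.sosfilt(sos, flat, axis=0, zi=zi)
    return replace(seq, data=out.reshape(seq.data.shape))


def smooth_sequence(seq: SkeletonSequence, config: PrepConfig | None = None) -> SkeletonSequence:
    """Apply the Savitzky-Golay stage (noisy stream only) to all channels."""
    config = config or PrepConfig()
    if config.savgol_window % 2 == 0 or config.savgol_window <= config.savgol_degree:
        raise SignalPrepError("window must be odd and larger than the polynomial degree")
    out = signal.savgol_filter(
        seq.data.reshape(len(seq), -1),
        window_length=config.savgol_window,
        polyorder=config.savgol_degree,
        axis=0,
    )
    return replace(seq, data=out.reshape(seq.data.shape))


def align_lag(
    noisy: SkeletonSequence, reference: SkeletonSequence, max_lag_s: float = 3.0
) -> int:
    """Alignment lag (frames) from right-wrist Z cross-correlation.

    Both sequences must share a sampling rate.  The returned lag ``l``
    maximizes the normalized cross-correlation of the mean-removed signals
    and satisfies ``reference[i] ~ noisy[i + l]``; equivalently a noisy
    stream delayed by ``l`` frames yields lag ``+l``.

    The search is bounded by ``max_lag_s`` because simultaneous recordings
    start within a few seconds of each other (a synchronization gesture);
    an unbounded search on near-periodic motion would risk snapping to a
    whole-period offset.
    """
    if abs(noisy.nominal_rate - reference.nominal_rate) > 1e-9:
        raise SignalPrepError("streams must be resampled to a common rate before alignment")
    a = noisy.joint(JointName.RIGHT_WRIST)[:, 2].astype(float)
    b = reference.joint(JointName.RIGHT_WRIST)[:, 2].astype(float)
    a = a - a.mean()
    b = b - b.mean()
    if a.std() == 0 or b.std() == 0:
        raise SignalPrepError("zero-variance right-wrist Z signal; correlation undefined")
    min_overlap = max(int(round(2.0 * noisy.nominal_rate)), 2)
    max_lag = min(len(a), len(b)) - min_overlap
    if max_lag < 0:
        raise SignalPrepError("streams overlap by less than two seconds")
    max_lag = min(max_lag, int(round(max_lag_s * noisy.nominal_rate)))
    best_lag, best_score = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = a[lag:], b
        else:
            x, y = a, b[-lag:]
        m = min(len(x), len(y))
        x, y = x[:m], y[:m]
        denom = np.linalg.norm(x) * np.linalg.norm(y)
        if denom == 0:
            continue
        score = float(np.dot(x, y) / denom)
        if score > best_score:
            best_lag, best_score = lag, score
    return best_lag


def pair_streams(
    noisy: SkeletonSequence, reference: SkeletonSequence, lag: int | None = None
) -> list[PairedFrame]:
    """Apply an alignment lag and zip the overlapping frames into pairs."""
    if lag is None:
        lag = align_lag(noisy, reference)
    if lag >= 0:
        k, q = noisy.slice(lag, len(noisy)), reference
    else:
        k, q = noisy, reference.slice(-lag, len(reference))
    n = min(len(k), len(q))
    times = q.times[:n] if lag >= 0 else k.times[:n]
    return [
        PairedFrame(SkeletonFrame(float(t), kx), SkeletonFrame(float(t), qx))
        for t, kx, qx in zip(times, k.data[:n], q.data[:n])
    ]


def screen_outliers(
    pairs: list[PairedFrame], threshold_m: float = 0.30
) -> tuple[list[PairedFrame], list[PairedFrame], np.ndarray]:
    """Reject pairs whose worst per-joint K-Q distance exceeds a gate.

    Automated surrogate for manual outlier cleaning of paired recordings.
    Returns (kept, rejected, kept_mask).
    """
    if not pairs:
        return [], [], np.zeros(0, dtype=bool)
    k = np.stack([p.k_frame.xyz for p in pairs])
    q = np.stack([p.q_frame.xyz for p in pairs])
    worst = np.linalg.norm(k - q, axis=2).max(axis=1)
    keep = worst <= threshold_m
    kept = [p for p, ok in zip(pairs, keep) if ok]
    rejected = [p for p, ok in zip(pairs, keep) if not ok]
    return kept, rejected, keep


def preprocess_pair(
    noisy: SkeletonSequence,
    reference: SkeletonSequence,
    config: PrepConfig | None = None,
) -> list[PairedFrame]:
    """Full paired-stream pipeline: filter, smooth (noisy), resample, align, screen."""
    config = config or PrepConfig()
    k = filter_sequence(noisy, config)
    k = smooth_sequence(k, config)
    q = filter_sequence(reference, config)
    k = resample_uniform(k, config.resample_rate_hz)
    q = resample_uniform(q, config.resample_rate_hz)
    pairs = pair_streams(k, q)
    # drop the smoother's endpoint-fit region at both ends of the trial
    trim = config.savgol_window // 2
    if len(pairs) > 2 * trim:
        pairs = pairs[trim:-trim]
    kept, _, _ = screen_outliers(pairs, config.outlier_threshold_m)
    return kept


def preprocess_single(seq: SkeletonSequence, config: PrepConfig | None = None) -> SkeletonSequence:
    """Single-stream (assessment) pipeline: filter, smooth, resample."""
    config = config or PrepConfig()
    out = filter_sequence(seq, config)
    out = smooth_sequence(out, config)
    return resample_uniform(out, config.resample_rate_hz)
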