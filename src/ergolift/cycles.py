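"""Lift-cycle detection and per-trial parameter summaries.

A lift cycle runs from an origin (local minimum of the mean hand height) to
a destination (the following local maximum).  Candidate destinations are
found on a band-passed copy of the hand-height signal restricted to natural
human lifting frequencies, then snapped to the nearest extremum of the
smoothed unfiltered signal; each origin is the lowest smoothed hand height
between consecutive destinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .equation import Coupling, DurationClass, NioshParameters
from .geometry import FrameParameters, sequence_parameters, travel_distance
from .signal_prep import Channel
from .skeleton import JOINT_INDEX, JointName, SkeletonSequence


class CycleError(ValueError):
    """No usable lift cycles could be extracted."""


@dataclass
class CycleConfig:
    """Tunable cycle-detection settings."""

    band_hz: tuple[float, float] = (0.05, 1.0)  # natural lifting band, 3-60 lifts/min
    min_amplitude_m: float = 0.05  # gate against spurious micro-cycles
    smooth_window: int = 15  # Savitzky-Golay window for the snap signal
    hand_anchor: str = "wrist"


@dataclass(frozen=True)
class LiftCycle:
    origin_index: int
    destination_index: int
    start_time: float
    end_time: float


@dataclass
class TrialSummary:
    """Mean lifting-equation parameters over all detected cycles."""

    parameters: NioshParameters
    n_cycles: int
    per_cycle: list[tuple[FrameParameters, FrameParameters]]
    cycles: list[LiftCycle] = field(default_factory=list)
    corrected: bool = False


def hand_height_signal(seq: SkeletonSequence, hand_anchor: str = "wrist") -> Channel:
    """Mean Z coordinate of the two hand-anchor joints, per frame."""
    if hand_anchor == "wrist":
        rows = [JOINT_INDEX[JointName.LEFT_WRIST], JOINT_INDEX[JointName.RIGHT_WRIST]]
    elif hand_anchor == "hand":
        rows = [JOINT_INDEX[JointName.LEFT_HAND], JOINT_INDEX[JointName.RIGHT_HAND]]
    else:
        raise ValueError(f"unknown hand anchor {hand_anchor!r}")
    values = seq.data[:, rows, 2].mean(axis=1)
    return Channel(values=values, rate=seq.nominal_rate, label=("hands", "z"))


def _bandpass(values: np.ndarray, rate: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    nyq = rate / 2.0
    hi = min(hi, 0.95 * nyq)
    # remove the mean first so the slow roll-off of a short recording does
    # not dominate, then apply a zero-phase band-pass
    x = values - values.mean()
    sos = sps.butter(2, [lo, hi], btype="band", fs=rate, output="sos")
    padlen = min(len(x) - 1, 3 * int(rate / lo))
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def _smooth_for_snap(values: np.ndarray, window: int) -> np.ndarray:
    window = min(window, len(values) - (1 - len(values) % 2))
    if window < 5:
        return values
    if window % 2 == 0:
        window -= 1
    return sps.savgol_filter(values, window_length=window, polyorder=3)


def detect_cycles(seq: SkeletonSequence, config: CycleConfig | None = None) -> list[LiftCycle]:
    """Detect lift cycles from the hand-height trajectory.

    Returns an empty list (not an error) when no extrema are found, e.g. on
    a constant signal.
    """
    config = config or CycleConfig()
    z = hand_height_signal(seq, config.hand_anchor).values
    n = len(z)
    rate = seq.nominal_rate
    if n < 8 or np.ptp(z) < 1e-12:
        return []
    zb = _bandpass(z, rate, config.band_hz)
    if np.ptp(zb) < 1e-9:
        return []
    zs = _smooth_for_snap(z, config.smooth_window)

    # candidate destinations: maxima of the band-passed signal
    prominence = 0.25 * np.std(zb)
    peaks, _ = sps.find_peaks(zb, prominence=prominence)
    if len(peaks) == 0:
        return []

    # dominant period from band-passed zero crossings -> snap window
    crossings = np.nonzero(np.diff(np.signbit(zb)))[0]
    if len(crossings) >= 2:
        period = 2.0 * np.mean(np.diff(crossings))
    else:
        period = n / max(len(peaks), 1)
    half_window = max(2, int(round(period / 4.0)))

    # snap each destination to the nearest smoothed-signal maximum
    dests: list[int] = []
    for p in peaks:
        lo, hi = max(0, p - half_window), min(n, p + half_window + 1)
        snapped = lo + int(np.argmax(zs[lo:hi]))
        if not dests or snapped - dests[-1] > half_window:
            dests.append(snapped)

    cycles: list[LiftCycle] = []
    prev_dest = 0
    for d in dests:
        if d <= prev_dest:
            continue
        origin = prev_dest + int(np.argmin(zs[prev_dest:d]))
        if zs[d] - zs[origin] >= config.min_amplitude_m and origin < d:
            cycles.append(
                LiftCycle(
                    origin_index=origin,
                    destination_index=d,
                    start_time=float(seq.times[origin]),
                    end_time=float(seq.times[d]),
                )
            )
        prev_dest = d
    return cycles


def lifting_frequency(cycles: list[LiftCycle], duration_s: float) -> float:
    """Lifts per minute from a cycle count over a recording span."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return 60.0 * len(cycles) / duration_s


def summarize_trial(
    seq: SkeletonSequence,
    model=None,
    config: CycleConfig | None = None,
    duration_class: DurationClass | str = DurationClass.SHORT,
    coupling: Coupling | str = Coupling.FAIR,
) -> TrialSummary:
    """Per-trial mean lifting-equation parameters over detected cycles.

    H and A are evaluated at each cycle origin (the beginning of the lift),
    V at origin and destination, and D from the origin/destination pair;
    each is averaged over cycles.  When an error-correction results object
    is supplied, its per-frame corrected parameter series replaces the raw
    geometric series before extraction.
    """
    config = config or CycleConfig()
    cycles = detect_cycles(seq, config)
    if not cycles:
        raise CycleError(
            "no lift cycles detected; check hand-height excursion "
            f"(min amplitude {config.min_amplitude_m} m) and the band "
            f"{config.band_hz} Hz"
        )
    if model is not None:
        params = model.correct_sequence(seq, hand_anchor=config.hand_anchor)
        cols = {"H": "H_corrected", "V": "V_corrected", "A": "A_corrected"}
    else:
        params = sequence_parameters(seq, hand_anchor=config.hand_anchor)
        cols = {"H": "H", "V": "V", "A": "A"}

    h_vals, v_vals, d_vals, a_vals = [], [], [], []
    per_cycle: list[tuple[FrameParameters, FrameParameters]] = []
    for c in cycles:
        o, d = c.origin_index, c.destination_index
        h_o = float(params[cols["H"]].iloc[o])
        v_o = float(params[cols["V"]].iloc[o])
        a_o = float(np.clip(params[cols["A"]].iloc[o], 0.0, 180.0))
        v_d = float(params[cols["V"]].iloc[d])
        h_vals.append(h_o)
        v_vals.append(v_o)
        a_vals.append(a_o)
        d_vals.append(travel_distance(v_o, v_d))
        per_cycle.append(
            (
                FrameParameters(H=h_o, V=v_o, A=a_o, time=c.start_time),
                FrameParameters(
                    H=float(params[cols["H"]].iloc[d]),
                    V=v_d,
                    A=float(np.clip(params[cols["A"]].iloc[d], 0.0, 180.0)),
                    time=c.end_time,
                ),
            )
        )
    frequency = lifting_frequency(cycles, seq.duration)
    summary = NioshParameters(
        H=float(np.mean(h_vals)),
        V=float(np.mean(v_vals)),
        D=float(np.mean(d_vals)),
        A=float(np.mean(a_vals)),
        F=frequency,
        duration_class=DurationClass.coerce(duration_class),
        coupling=Coupling.coerce(coupling),
    )
    return TrialSummary(
        parameters=summary,
        n_cycles=len(cycles),
        per_cycle=per_cycle,
        cycles=cycles,
        corrected=model is not None,
    )
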