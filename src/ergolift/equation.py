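"""The revised NIOSH lifting equation.

RWL = LC * HM * VM * DM * AM * FM * CM with LC = 23 kg.  The four analytic
multipliers are::

    HM = 25 / H          (H in cm, clamped to [25, 63])
    VM = 1 - 0.003|V-75| (V in cm, clamped to [0, 175])
    DM = 0.82 + 4.5 / D  (D in cm, minimum 25, maximum 175)
    AM = 1 - 0.0032 A    (A in degrees, zero above 135)

FM and CM come from the standard published lookup tables (frequency x work
duration, with a hand-height split, and grip quality x hand height
respectively).  The Lifting Index LI = load / RWL flags increased low-back
injury risk when it exceeds 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

LOAD_CONSTANT_KG = 23.0


class DurationClass(str, Enum):
    """Work-duration category of the frequency-multiplier table."""

    SHORT = "1h"  # <= 1 hour
    MODERATE = "2h"  # <= 2 hours
    LONG = "8h"  # <= 8 hours

    @classmethod
    def coerce(cls, value: "DurationClass | str") -> "DurationClass":
        if isinstance(value, cls):
            return value
        normalized = str(value).lower().lstrip("<=").strip()
        for member in cls:
            if normalized == member.value:
                return member
        raise ValueError(f"unknown duration class {value!r}; expected one of 1h/2h/8h")


class Coupling(str, Enum):
    GOOD = "good"
    FAIR = "fair"
    POOR = "poor"

    @classmethod
    def coerce(cls, value: "Coupling | str") -> "Coupling":
        if isinstance(value, cls):
            return value
        normalized = str(value).lower()
        aliases = {"g": "good", "f": "fair", "p": "poor"}
        normalized = aliases.get(normalized, normalized)
        try:
            return cls(normalized)
        except ValueError:
            raise ValueError(f"unknown coupling class {value!r}") from None


# Standard revised-equation frequency-multiplier table (NIOSH Applications
# Manual, 1994 revision): rows are lifts/min, columns (V<75 cm, V>=75 cm)
# per work-duration class.
_FM_FREQUENCIES = (0.2, 0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15)
_FM_TABLE: dict[DurationClass, tuple[tuple[float, float], ...]] = {
    DurationClass.SHORT: (
        (1.00, 1.00), (0.97, 0.97), (0.94, 0.94), (0.91, 0.91), (0.88, 0.88),
        (0.84, 0.84), (0.80, 0.80), (0.75, 0.75), (0.70, 0.70), (0.60, 0.60),
        (0.52, 0.52), (0.45, 0.45), (0.41, 0.41), (0.37, 0.37), (0.00, 0.34),
        (0.00, 0.31), (0.00, 0.28),
    ),
    DurationClass.MODERATE: (
        (0.95, 0.95), (0.92, 0.92), (0.88, 0.88), (0.84, 0.84), (0.79, 0.79),
        (0.72, 0.72), (0.60, 0.60), (0.50, 0.50), (0.42, 0.42), (0.35, 0.35),
        (0.30, 0.30), (0.26, 0.26), (0.00, 0.23), (0.00, 0.21), (0.00, 0.00),
        (0.00, 0.00), (0.00, 0.00),
    ),
    DurationClass.LONG: (
        (0.85, 0.85), (0.81, 0.81), (0.75, 0.75), (0.65, 0.65), (0.55, 0.55),
        (0.45, 0.45), (0.35, 0.35), (0.27, 0.27), (0.22, 0.22), (0.18, 0.18),
        (0.00, 0.15), (0.00, 0.13), (0.00, 0.00), (0.00, 0.00), (0.00, 0.00),
        (0.00, 0.00), (0.00, 0.00),
    ),
}

# Coupling multiplier: (V<75 cm, V>=75 cm)
_CM_TABLE: dict[Coupling, tuple[float, float]] = {
    Coupling.GOOD: (1.00, 1.00),
    Coupling.FAIR: (0.95, 1.00),
    Coupling.POOR: (0.90, 0.90),
}


@dataclass(frozen=True)
class NioshParameters:
    """Task parameters of one lifting job."""

    H: float  # horizontal location, cm
    V: float  # vertical location at lift origin, cm
    D: float  # vertical travel distance, cm
    A: float  # asymmetry angle, degrees
    F: float  # lifting frequency, lifts/min
    duration_class: DurationClass = DurationClass.SHORT
    coupling: Coupling = Coupling.FAIR

    def __post_init__(self) -> None:
        object.__setattr__(self, "duration_class", DurationClass.coerce(self.duration_class))
        object.__setattr__(self, "coupling", Coupling.coerce(self.coupling))
        if self.F < 0:
            raise ValueError("lifting frequency must be non-negative")
        for name in ("H", "V", "D", "A"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")


@dataclass(frozen=True)
class Multipliers:
    HM: float
    VM: float
    DM: float
    AM: float
    FM: float
    CM: float

    def product(self) -> float:
        return self.HM * self.VM * self.DM * self.AM * self.FM * self.CM

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("HM", "VM", "DM", "AM", "FM", "CM")}


@dataclass(frozen=True)
class RwlResult:
    rwl: float  # kg
    multipliers: Multipliers
    parameters: NioshParameters
    li: float | None = None  # lifting index, when a load weight was given
    unbounded_risk: bool = False  # RWL = 0 with a positive load

    def as_dict(self) -> dict:
        return {
            "rwl_kg": self.rwl,
            "multipliers": self.multipliers.as_dict(),
            "parameters": {
                "H_cm": self.parameters.H,
                "V_cm": self.parameters.V,
                "D_cm": self.parameters.D,
                "A_deg": self.parameters.A,
                "F_per_min": self.parameters.F,
                "duration_class": self.parameters.duration_class.value,
                "coupling": self.parameters.coupling.value,
            },
            "lifting_index": None if self.li is None else (self.li if math.isfinite(self.li) else "inf"),
            "unbounded_risk": self.unbounded_risk,
        }


def horizontal_multiplier(h_cm: float, max_h_cm: float | None = None) -> float:
    """HM = 25/H; loads closer than 25 cm get full credit.

    The equation's core formula keeps the 25/H decay at any reach.  Passing
    ``max_h_cm`` (the applications-manual tables use 63 cm) zeroes the
    multiplier beyond a maximum reach instead.
    """
    if max_h_cm is not None and h_cm > max_h_cm:
        return 0.0
    return 1.0 if h_cm < 25.0 else 25.0 / h_cm


def vertical_multiplier(v_cm: float) -> float:
    """VM = 1 - 0.003|V - 75|; negative sensor V clamps to the floor."""
    v = max(v_cm, 0.0)
    if v > 175.0:
        return 0.0
    return 1.0 - 0.003 * abs(v - 75.0)


def distance_multiplier(d_cm: float) -> float:
    """DM = 0.82 + 4.5/D with a 25 cm minimum travel and 175 cm maximum."""
    if d_cm < 0:
        raise ValueError("travel distance must be non-negative")
    if d_cm > 175.0:
        return 0.0
    d = max(d_cm, 25.0)
    return 0.82 + 4.5 / d


def asymmetry_multiplier(a_deg: float) -> float:
    """AM = 1 - 0.0032 A, zero beyond 135 degrees of twist."""
    if not 0.0 <= a_deg <= 180.0:
        raise ValueError("asymmetry angle must lie in [0, 180] degrees")
    if a_deg > 135.0:
        return 0.0
    return 1.0 - 0.0032 * a_deg


def frequency_multiplier(
    f_per_min: float, duration_class: DurationClass | str = DurationClass.SHORT, v_cm: float = 0.0
) -> float:
    """FM from the published frequency/duration table.

    Frequencies between tabulated rows round to the nearest row; above the
    table's 15 lifts/min ceiling the multiplier is zero.
    """
    if f_per_min < 0:
        raise ValueError("frequency must be non-negative")
    duration = DurationClass.coerce(duration_class)
    if f_per_min > _FM_FREQUENCIES[-1]:
        return 0.0
    row = min(range(len(_FM_FREQUENCIES)), key=lambda i: abs(f_per_min - _FM_FREQUENCIES[i]))
    lo, hi = _FM_TABLE[duration][row]
    return lo if v_cm < 75.0 else hi


def coupling_multiplier(coupling: Coupling | str, v_cm: float) -> float:
    """CM from the grip-quality table (fair grips are penalized below 75 cm)."""
    lo, hi = _CM_TABLE[Coupling.coerce(coupling)]
    return lo if v_cm < 75.0 else hi


def compute_multipliers(p: NioshParameters) -> Multipliers:
    return Multipliers(
        HM=horizontal_multiplier(p.H),
        VM=vertical_multiplier(p.V),
        DM=distance_multiplier(p.D),
        AM=asymmetry_multiplier(p.A),
        FM=frequency_multiplier(p.F, p.duration_class, p.V),
        CM=coupling_multiplier(p.coupling, p.V),
    )


def recommended_weight_limit(p: NioshParameters, load_kg: float | None = None) -> RwlResult:
    """RWL (kg) for a lifting task; with a load weight, also the LI."""
    multipliers = compute_multipliers(p)
    rwl = LOAD_CONSTANT_KG * multipliers.product()
    li = None
    unbounded = False
    if load_kg is not None:
        li = lifting_index(load_kg, rwl)
        unbounded = math.isinf(li)
    return RwlResult(rwl=rwl, multipliers=multipliers, parameters=p, li=li, unbounded_risk=unbounded)


def lifting_index(load_kg: float, rwl_kg: float) -> float:
    """LI = load / RWL; a zero RWL flags unbounded risk as +inf."""
    if load_kg < 0:
        raise ValueError("load weight must be non-negative")
    if rwl_kg == 0.0:
        return math.inf if load_kg > 0 else 0.0
    return load_kg / rwl_kg
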