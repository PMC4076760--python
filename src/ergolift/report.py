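"""End-to-end lifting-hazard assessment of a skeleton recording."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .correction import ErrorCorrectionResults
from .cycles import CycleConfig, TrialSummary, summarize_trial
from .equation import Coupling, DurationClass, RwlResult, recommended_weight_limit
from .signal_prep import PrepConfig, preprocess_single
from .skeleton import read_sequence


class AssessmentError(RuntimeError):
    """Assessment could not be completed (bad input, no cycles, schema)."""


@dataclass
class AssessmentReport:
    """Raw (and optionally error-corrected) lifting-equation assessment."""

    subject_id: str
    trial_id: str
    n_frames: int
    n_cycles: int
    raw: RwlResult
    corrected: RwlResult | None = None
    load_kg: float | None = None

    def as_dict(self) -> dict:
        out = {
            "subject_id": self.subject_id,
            "trial_id": self.trial_id,
            "n_frames": self.n_frames,
            "n_cycles": self.n_cycles,
            "load_kg": self.load_kg,
            "raw": self.raw.as_dict(),
        }
        if self.corrected is not None:
            out["corrected"] = self.corrected.as_dict()
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.as_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"Lifting assessment — subject {self.subject_id or '?'} "
            f"trial {self.trial_id or '?'}",
            f"frames: {self.n_frames}, lift cycles: {self.n_cycles}",
            "",
        ]
        blocks = [("raw", self.raw)]
        if self.corrected is not None:
            blocks.append(("corrected", self.corrected))
        for label, res in blocks:
            p = res.parameters
            lines.append(
                f"[{label}] H={p.H:.1f} cm  V={p.V:.1f} cm  D={p.D:.1f} cm  "
                f"A={p.A:.1f} deg  F={p.F:.2f}/min"
            )
            m = res.multipliers
            lines.append(
                f"        HM={m.HM:.3f} VM={m.VM:.3f} DM={m.DM:.3f} "
                f"AM={m.AM:.3f} FM={m.FM:.2f} CM={m.CM:.2f}"
            )
            li = "" if res.li is None else f"  LI={res.li:.2f}"
            lines.append(f"        RWL = {res.rwl:.2f} kg{li}")
        return "\n".join(lines)


def _summary_to_rwl(summary: TrialSummary, load_kg: float | None) -> RwlResult:
    return recommended_weight_limit(summary.parameters, load_kg=load_kg)


def run_assessment(
    recording_path: str | Path,
    model_path: str | Path | None = None,
    prep_config: PrepConfig | None = None,
    cycle_config: CycleConfig | None = None,
    load_kg: float | None = None,
    duration_class: DurationClass | str = DurationClass.SHORT,
    coupling: Coupling | str = Coupling.FAIR,
    preprocess: bool = True,
) -> AssessmentReport:
    """Assess a skeleton recording: preprocess, segment lifts, score RWL/LI.

    With a model path, error-corrected parameters and a corrected RWL are
    reported alongside the raw ones.
    """
    recording_path = Path(recording_path)
    if not recording_path.exists():
        raise AssessmentError(f"recording not found: {recording_path}")
    seq = read_sequence(recording_path)
    if preprocess:
        seq = preprocess_single(seq, prep_config or PrepConfig())
    results = ErrorCorrectionResults.load(model_path) if model_path else None

    kwargs = dict(config=cycle_config, duration_class=duration_class, coupling=coupling)
    try:
        raw_summary = summarize_trial(seq, model=None, **kwargs)
        corrected_summary = (
            summarize_trial(seq, model=results, **kwargs) if results is not None else None
        )
    except ValueError as exc:
        raise AssessmentError(str(exc)) from exc

    return AssessmentReport(
        subject_id=seq.subject_id,
        trial_id=seq.trial_id,
        n_frames=len(seq),
        n_cycles=raw_summary.n_cycles,
        raw=_summary_to_rwl(raw_summary, load_kg),
        corrected=None if corrected_summary is None else _summary_to_rwl(corrected_summary, load_kg),
        load_kg=load_kg,
    )
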