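"""Pipeline configuration and the composed assessment workflow.

An assessment (baseline, post, or followup) runs the full pipeline on one
set of recorded files: gait-event detection from the trajectories, the
spatiotemporal summary in the 2-8 m walkway window, and — when EMG and a
stimulation schedule are provided — per-channel envelopes and the
stimulated/non-stimulated activity ratios for the muscles targeted in
training.  ``compare_assessments`` then reports signed changes of every
parameter versus baseline.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import emg as emg_mod
from . import io, sequencer, spatiotemporal
from .core import SIDES, channel_label
from .events import EventDetectorConfig, detect_events

log = logging.getLogger(__name__)

ASSESSMENT_LABELS = ("baseline", "post", "followup")

#: Stimulated muscle group -> EMG muscle used for the activity ratio.
#: (Gluteii have no recorded EMG channel.)
RATIO_MUSCLE_MAP = {
    "quadriceps": "VL",
    "hamstrings": "ST",
    "gastrocnemius": "GAM",
    "tibialis_anterior": "TA",
}


@dataclass
class PipelineConfig:
    trajectories: str
    label: str = "baseline"
    emg: str | None = None
    schedule: str | None = None
    events: str | None = None          # use recorded events instead of detecting
    session_log: str | None = None
    window_m: tuple[float, float] = spatiotemporal.DEFAULT_WINDOW_M
    detector: EventDetectorConfig = field(default_factory=EventDetectorConfig)
    filter_spec: emg_mod.FilterSpec = field(default_factory=emg_mod.FilterSpec)

    def __post_init__(self) -> None:
        if self.label not in ASSESSMENT_LABELS:
            raise ValueError(
                f"label {self.label!r} must be one of {ASSESSMENT_LABELS}"
            )
        for name in ("trajectories", "emg", "schedule", "events", "session_log"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        detector = EventDetectorConfig(**payload.pop("detector", {}))
        filter_spec = emg_mod.FilterSpec(**payload.pop("filter_spec", {}))
        window = tuple(payload.pop("window_m", spatiotemporal.DEFAULT_WINDOW_M))
        return cls(detector=detector, filter_spec=filter_spec,
                   window_m=window, **payload)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise errors with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_assessment(config: PipelineConfig) -> dict:
    """Run one full assessment and return a JSON-serializable report."""
    report: dict = {"schema_version": io.SCHEMA_VERSION, "label": config.label}

    with _stage("trajectories"):
        trial = io.read_trajectories_csv(config.trajectories)

    with _stage("gait_events"):
        if config.events is not None:
            events = io.read_events_csv(config.events, source="truth")
        else:
            events = detect_events(trial, config.detector)
        report["events"] = {
            side: {
                "foot_contact": [round(float(t), 6) for t in events.contacts[side]],
                "foot_off": [round(float(t), 6) for t in events.offs[side]],
            }
            for side in SIDES
        }

    with _stage("spatiotemporal"):
        summary = spatiotemporal.summarize(trial, events, config.window_m)
        report["spatiotemporal"] = summary.to_dict()

    if config.emg is not None:
        with _stage("emg"):
            recording = io.read_emg_csv(config.emg)
            schedule = (io.read_schedule_json(config.schedule)
                        if config.schedule else None)
            ratios = []
            envelopes = {}
            for stim_muscle, emg_muscle in RATIO_MUSCLE_MAP.items():
                for side in SIDES:
                    label = channel_label(emg_muscle, side)
                    if label not in recording.channels:
                        continue
                    env = emg_mod.process_channel(
                        recording, label, events, spec=config.filter_spec
                    )
                    envelopes[label] = {
                        "n_strides": int(env.stride_matrix.shape[0]),
                        "n_excluded": len(env.excluded_strides),
                        "mean_profile": [
                            round(float(v), 6) for v in env.mean_profile()
                        ],
                    }
                    if schedule is not None:
                        windows = sequencer.cycle_window(schedule, stim_muscle, side)
                        r = emg_mod.stim_ratio(env, windows,
                                               assessment=config.label)
                        ratios.append(r.to_dict())
            report["emg"] = {"envelopes": envelopes, "stim_ratios": ratios}

    if config.session_log is not None:
        with _stage("feasibility"):
            from . import feasibility as feas

            log_df = io.read_session_log_csv(config.session_log)
            planned = int(log_df.groupby("participant")["session"].count().max())
            rep = feas.feasibility_report(log_df, planned)
            report["feasibility"] = rep.to_dict()

    return report


def compare_assessments(reports: list[dict]) -> dict:
    """Signed longitudinal changes versus the baseline report."""
    by_label = {r["label"]: r for r in reports}
    if len(by_label) < 2:
        raise ValueError("need at least two reports with distinct labels")
    if "baseline" not in by_label:
        raise ValueError("a baseline report is required")
    base = by_label["baseline"]["spatiotemporal"]
    out: dict = {"schema_version": io.SCHEMA_VERSION, "comparisons": {}}
    for label in ("post", "followup"):
        if label not in by_label:
            continue
        cur = by_label[label]["spatiotemporal"]
        out["comparisons"][label] = {
            key: cur[key] - base[key]
            for key in ("walking_speed_ms", "step_length_mean_cm",
                        "step_width_mean_cm", "cadence_spm")
        }

    # ratio changes via the EMG pipeline, when available
    ratios = []
    for r in by_label.values():
        for d in r.get("emg", {}).get("stim_ratios", []):
            ratios.append(emg_mod.StimRatio(**d))
    if ratios and len({r.assessment for r in ratios}) >= 2:
        table = emg_mod.ratio_change(ratios)
        out["ratio_changes"] = [
            {k: (None if isinstance(v, float) and np.isnan(v) else v)
             for k, v in row.items()}
            for row in table.to_dict(orient="records")
        ]
    return out


__all__ = [
    "ASSESSMENT_LABELS",
    "RATIO_MUSCLE_MAP",
    "PipelineConfig",
    "run_assessment",
    "compare_assessments",
]
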