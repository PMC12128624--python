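"""Spatiotemporal gait parameters from a walkway pass.

Step locations are the median ankle position (AP and ML, in cm) during each
single-support phase.  Step length is the signed AP difference and step
width the absolute ML difference of consecutive, alternating-side step
locations.  Cadence pools foot contacts of both feet.  Walking speed is
measured between the 2 m and 8 m walkway lines to exclude acceleration and
deceleration; steps belong to the measurement window when the later step
location's AP position lies in [2 m, 8 m).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import GaitEventSet, SIDES, TrajectoryTrial, ankle_point
from .events import single_support_intervals

log = logging.getLogger(__name__)

#: Walkway measurement window in metres.
DEFAULT_WINDOW_M = (2.0, 8.0)


@dataclass
class StepLocation:
    side: str
    ap_cm: float
    ml_cm: float
    interval: tuple[float, float]

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ap_cm) and np.isfinite(self.ml_cm)):
            raise ValueError("step location coordinates must be finite")
        if self.interval[1] <= self.interval[0]:
            raise ValueError("step location interval must have positive length")


@dataclass
class SpatiotemporalSummary:
    walking_speed_ms: float
    step_lengths_cm: list[float]
    step_widths_cm: list[float]
    cadence_spm: float
    n_steps: int
    window_m: tuple[float, float] = DEFAULT_WINDOW_M

    @property
    def step_length_mean_cm(self) -> float:
        return float(np.mean(self.step_lengths_cm)) if self.step_lengths_cm else float("nan")

    @property
    def step_width_mean_cm(self) -> float:
        return float(np.mean(self.step_widths_cm)) if self.step_widths_cm else float("nan")

    def to_dict(self) -> dict:
        return {
            "walking_speed_ms": self.walking_speed_ms,
            "step_length_mean_cm": self.step_length_mean_cm,
            "step_lengths_cm": list(map(float, self.step_lengths_cm)),
            "step_width_mean_cm": self.step_width_mean_cm,
            "step_widths_cm": list(map(float, self.step_widths_cm)),
            "cadence_spm": self.cadence_spm,
            "n_steps": self.n_steps,
            "window_m": list(self.window_m),
        }


def step_locations(trial: TrajectoryTrial, events: GaitEventSet) -> list[StepLocation]:
    """One step location per single-support interval, both sides, time ordered."""
    locations: list[StepLocation] = []
    for side in SIDES:
        ankle = trial.point(ankle_point(side))
        for (a, b) in single_support_intervals(events, side):
            m = (trial.time >= a) & (trial.time <= b)
            if not np.any(m):
                log.warning(
                    "single-support interval (%.3f, %.3f) of the %s side contains "
                    "no trajectory samples; skipped", a, b, side,
                )
                continue
            locations.append(StepLocation(
                side=side,
                ap_cm=float(np.median(ankle[m, 0]) * 100),
                ml_cm=float(np.median(ankle[m, 1]) * 100),
                interval=(a, b),
            ))
    locations.sort(key=lambda s: s.interval[0])
    return locations


def step_length_width(
    locations: list[StepLocation],
) -> list[dict]:
    """Per-step length (signed, cm) and width (cm) from consecutive locations.

    Consecutive same-side locations are skipped (and logged); negative step
    lengths are kept but flagged.
    """
    if len(locations) < 2:
        raise ValueError("need at least two step locations")
    steps = []
    for prev, cur in zip(locations[:-1], locations[1:]):
        if prev.side == cur.side:
            log.warning(
                "two consecutive %s-side step locations at %.3fs and %.3fs; "
                "pair skipped", cur.side, prev.interval[0], cur.interval[0],
            )
            continue
        length = cur.ap_cm - prev.ap_cm
        if length < 0:
            log.warning("negative (backward) step of %.1f cm at %.3fs",
                        length, cur.interval[0])
        steps.append({
            "side": cur.side,
            "length_cm": float(length),
            "width_cm": float(abs(cur.ml_cm - prev.ml_cm)),
            "ap_cm": cur.ap_cm,
            "time_s": cur.interval[0],
            "backward": bool(length < 0),
        })
    return steps


def cadence(
    events: GaitEventSet, time_window: tuple[float, float] | None = None
) -> float:
    """Steps per minute from pooled foot contacts: (n-1) / span * 60."""
    t = events.pooled_contacts()
    if time_window is not None:
        t = t[(t >= time_window[0]) & (t <= time_window[1])]
    if t.size < 2:
        raise ValueError(
            f"cadence needs at least two pooled foot contacts, found {t.size}"
        )
    return float((t.size - 1) / (t[-1] - t[0]) * 60.0)


def line_crossing_time(trial: TrajectoryTrial, line_m: float) -> float:
    """Linearly interpolated time at which the spine base crosses ``line_m``."""
    x = trial.point("spine_base")[:, 0]
    if not (x.min() <= line_m <= x.max()):
        raise ValueError(
            f"walkway not fully traversed: spine base spans "
            f"[{x.min():.2f}, {x.max():.2f}] m, cannot cross the {line_m:.0f} m line"
        )
    # first upward crossing
    above = np.nonzero(x >= line_m)[0]
    i = int(above[0])
    if i == 0:
        return float(trial.time[0])
    x0, x1 = x[i - 1], x[i]
    frac = (line_m - x0) / (x1 - x0)
    return float(trial.time[i - 1] + frac * (trial.time[i] - trial.time[i - 1]))


def walking_speed(
    trial: TrajectoryTrial, window_m: tuple[float, float] = DEFAULT_WINDOW_M
) -> float:
    """Walkway-window speed: window length over the spine-base crossing times."""
    t_in = line_crossing_time(trial, window_m[0])
    t_out = line_crossing_time(trial, window_m[1])
    if t_out <= t_in:
        raise ValueError("walkway lines crossed out of order")
    return float((window_m[1] - window_m[0]) / (t_out - t_in))


def summarize(
    trial: TrajectoryTrial,
    events: GaitEventSet,
    window_m: tuple[float, float] = DEFAULT_WINDOW_M,
) -> SpatiotemporalSummary:
    """Assemble the spatiotemporal summary within the measurement window."""
    speed = walking_speed(trial, window_m)
    t_win = (line_crossing_time(trial, window_m[0]),
             line_crossing_time(trial, window_m[1]))
    cad = cadence(events, time_window=t_win)
    locs = step_locations(trial, events)
    steps = step_length_width(locs)
    lo, hi = window_m[0] * 100, window_m[1] * 100
    in_window = [s for s in steps if lo <= s["ap_cm"] < hi]
    if not in_window:
        raise ValueError("no steps inside the measurement window")
    return SpatiotemporalSummary(
        walking_speed_ms=speed,
        step_lengths_cm=[s["length_cm"] for s in in_window],
        step_widths_cm=[s["width_cm"] for s in in_window],
        cadence_spm=cad,
        n_steps=len(in_window),
        window_m=window_m,
    )


def diff_summaries(a: SpatiotemporalSummary, b: SpatiotemporalSummary) -> dict:
    """Signed per-parameter changes ``a - b`` (e.g. post minus baseline)."""
    return {
        "walking_speed_ms": a.walking_speed_ms - b.walking_speed_ms,
        "step_length_mean_cm": a.step_length_mean_cm - b.step_length_mean_cm,
        "step_width_mean_cm": a.step_width_mean_cm - b.step_width_mean_cm,
        "cadence_spm": a.cadence_spm - b.cadence_spm,
    }


__all__ = [
    "DEFAULT_WINDOW_M",
    "StepLocation",
    "SpatiotemporalSummary",
    "step_locations",
    "step_length_width",
    "cadence",
    "line_crossing_time",
    "walking_speed",
    "summarize",
    "diff_summaries",
]
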