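"""Multi-channel stimulation schedules and event-driven timelines.

A schedule stores, per (muscle, side), a pre-set onset and duration in
milliseconds after ipsilateral initial contact, a 50 Hz stimulation
frequency, and a pulse width in the 1-320 microsecond device range.  The
timeline realizes the schedule against detected gait events: each channel
turns on at ``contact + onset`` for its duration, and an active window is
truncated when the sequence restarted at the next ipsilateral contact
reaches that channel's onset (``next_contact + onset``).  Windows pending
after the last contact run to completion.

The default sequence follows the training protocol: gastrocnemius during
stance (propulsion), tibialis anterior in early swing (foot clearance),
quadriceps in mid swing (knee extension), hamstrings and gluteii in
terminal swing (leg stabilization, preventing knee overextension at
contact).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import GaitEventSet, SIDES, STIM_MUSCLES

log = logging.getLogger(__name__)

PULSE_WIDTH_RANGE_US = (1.0, 320.0)

#: Swing sub-phase boundaries as fractions of the swing phase:
#: early swing = [0, 0.4], mid swing = [0.4, 0.75], terminal swing = [0.75, 1].
DEFAULT_SWING_SPLITS = (0.4, 0.75)


@dataclass
class StimulationChannelSpec:
    muscle: str
    side: str
    onset_ms: float
    duration_ms: float
    frequency_hz: float = 50.0
    pulse_width_us: float = 150.0
    intensity_note: str = ""

    def __post_init__(self) -> None:
        if self.muscle not in STIM_MUSCLES:
            raise ValueError(
                f"unknown stimulation muscle {self.muscle!r}; expected one of "
                f"{STIM_MUSCLES}"
            )
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.onset_ms < 0:
            raise ValueError("onset_ms must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        lo, hi = PULSE_WIDTH_RANGE_US
        if not lo <= self.pulse_width_us <= hi:
            raise ValueError(
                f"pulse_width_us must lie in [{lo:.0f}, {hi:.0f}] microseconds"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.muscle, self.side)


@dataclass
class StimulationSchedule:
    channels: list[StimulationChannelSpec]
    cycle_duration_ms: float

    def __post_init__(self) -> None:
        if self.cycle_duration_ms <= 0:
            raise ValueError("cycle_duration_ms must be positive")
        keys = [c.key for c in self.channels]
        if len(set(keys)) != len(keys):
            raise ValueError("at most one channel spec per (muscle, side)")

    def channel(self, muscle: str, side: str) -> StimulationChannelSpec:
        for c in self.channels:
            if c.key == (muscle, side):
                return c
        raise KeyError(f"no channel for ({muscle}, {side})")


@dataclass
class StimulationTimeline:
    """Realized on-intervals ``[start_s, end_s]`` per (muscle, side)."""

    intervals: dict[tuple[str, str], list[tuple[float, float]]]

    def on_time(self, muscle: str, side: str) -> float:
        return float(sum(e - s for s, e in self.intervals.get((muscle, side), [])))


def default_schedule(
    stance_fraction: float,
    cycle_duration_ms: float,
    swing_splits: tuple[float, float] = DEFAULT_SWING_SPLITS,
    pulse_width_us: float = 150.0,
) -> StimulationSchedule:
    """Bilateral phase-to-muscle mapping derived from the stance fraction.

    Stance = [0, SF]; early/mid/terminal swing split the remaining cycle at
    the given swing fractions.  All onsets and durations are expressed in
    milliseconds of the nominal cycle.
    """
    if not 0 < stance_fraction < 1:
        raise ValueError("stance_fraction must lie in (0, 1)")
    s1, s2 = swing_splits
    if not 0 < s1 < s2 < 1:
        raise ValueError("swing_splits must satisfy 0 < s1 < s2 < 1")
    sf = stance_fraction
    swing = 1.0 - sf
    windows = {
        "gastrocnemius": (0.0, sf),
        "tibialis_anterior": (sf, sf + s1 * swing),
        "quadriceps": (sf + s1 * swing, sf + s2 * swing),
        "hamstrings": (sf + s2 * swing, 1.0),
        "gluteii": (sf + s2 * swing, 1.0),
    }
    channels = [
        StimulationChannelSpec(
            muscle=m,
            side=side,
            onset_ms=a * cycle_duration_ms,
            duration_ms=(b - a) * cycle_duration_ms,
            pulse_width_us=pulse_width_us,
        )
        for m, (a, b) in windows.items()
        for side in SIDES
    ]
    return StimulationSchedule(channels=channels,
                               cycle_duration_ms=cycle_duration_ms)


def realize_timeline(
    schedule: StimulationSchedule, events: GaitEventSet
) -> StimulationTimeline:
    """Realize the schedule as on-intervals driven by ipsilateral contacts."""
    intervals: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for spec in schedule.channels:
        contacts = events.contacts[spec.side]
        chan: list[tuple[float, float]] = []
        if contacts.size == 0:
            log.warning("no %s contacts: channel (%s, %s) has an empty timeline",
                        spec.side, spec.muscle, spec.side)
        onset = spec.onset_ms / 1000.0
        duration = spec.duration_ms / 1000.0
        for i, c in enumerate(contacts):
            start = float(c + onset)
            end = start + duration
            if i + 1 < contacts.size:
                end = min(end, float(contacts[i + 1] + onset))
            if end > start:
                chan.append((start, float(end)))
        intervals[spec.key] = chan
    return StimulationTimeline(intervals=intervals)


def cycle_window(
    schedule: StimulationSchedule, muscle: str, side: str
) -> list[tuple[float, float]]:
    """Channel on-window as gait-cycle fractions, split when it wraps."""
    spec = schedule.channel(muscle, side)
    cyc = schedule.cycle_duration_ms
    a = (spec.onset_ms / cyc) % 1.0
    d = min(spec.duration_ms / cyc, 1.0)
    b = a + d
    if b <= 1.0:
        return [(a, b)]
    return [(a, 1.0), (0.0, b - 1.0)]


def calibrate_intensity(
    recruitment,
    motor_threshold_level: float,
    max_level: float,
) -> tuple[float, float]:
    """Pulse-width bounds from a monotone recruitment curve on [1, 320] us.

    Returns the smallest pulse width whose response reaches the motor
    threshold and the largest whose response does not exceed ``max_level``.
    Raises when the threshold is unreachable within 320 us (the muscle
    cannot be stimulated) or when the bounds cross.
    """
    widths = np.arange(PULSE_WIDTH_RANGE_US[0], PULSE_WIDTH_RANGE_US[1] + 1)
    if callable(recruitment):
        resp = np.asarray([recruitment(w) for w in widths], dtype=float)
    else:
        w_in, r_in = recruitment
        resp = np.interp(widths, np.asarray(w_in, float), np.asarray(r_in, float))
    if np.any(np.diff(resp) < -1e-9):
        raise ValueError("recruitment curve must be non-decreasing")
    reach = np.nonzero(resp >= motor_threshold_level)[0]
    if reach.size == 0:
        raise ValueError(
            "muscle not stimulable: motor threshold not reached within "
            f"{PULSE_WIDTH_RANGE_US[1]:.0f} us"
        )
    lo = float(widths[reach[0]])
    below = np.nonzero(resp <= max_level)[0]
    if below.size == 0 or float(widths[below[-1]]) < lo:
        raise ValueError(
            f"no admissible pulse-width range: minimum {lo:.0f} us exceeds the "
            "maximum tolerated intensity"
        )
    return lo, float(widths[below[-1]])


__all__ = [
    "PULSE_WIDTH_RANGE_US",
    "DEFAULT_SWING_SPLITS",
    "StimulationChannelSpec",
    "StimulationSchedule",
    "StimulationTimeline",
    "default_schedule",
    "realize_timeline",
    "cycle_window",
    "calibrate_intensity",
]
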