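"""Shared containers for markerless gait trials, gait events, and surface EMG.

Axis convention: anterior = +x (metres from the 0 m walkway line),
medio-lateral = +y (leftward), vertical = +z.  All public step metrics are
reported in centimetres; times in seconds from the first trajectory sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SIDES = ("left", "right")

#: Muscles recorded with surface EMG (bilateral).
EMG_MUSCLES = ("TA", "GAM", "SOL", "PL", "RF", "VL", "ST")

#: Muscle groups targeted by the stimulation suit (bilateral).
STIM_MUSCLES = (
    "quadriceps",
    "hamstrings",
    "gluteii",
    "tibialis_anterior",
    "gastrocnemius",
)

#: Body points tracked by the markerless capture system.
BODY_POINTS = ("ankle_L", "ankle_R", "spine_base")

_ANKLE_FOR_SIDE = {"left": "ankle_L", "right": "ankle_R"}


class MissingBodyPointError(KeyError):
    """A required body point is absent from the trajectory trial."""


class InsufficientStridesError(ValueError):
    """Too few valid strides to run the requested computation."""


def other_side(side: str) -> str:
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}; expected one of {SIDES}")
    return "right" if side == "left" else "left"


def ankle_point(side: str) -> str:
    """Body-point name for a side's ankle."""
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}; expected one of {SIDES}")
    return _ANKLE_FOR_SIDE[side]


def channel_label(muscle: str, side: str) -> str:
    """EMG channel label, e.g. ``TA_L``."""
    if muscle not in EMG_MUSCLES:
        raise ValueError(f"unknown muscle {muscle!r}; expected one of {EMG_MUSCLES}")
    return f"{muscle}_{'L' if side == 'left' else 'R'}"


def parse_channel_label(label: str) -> tuple[str, str]:
    muscle, _, tag = label.rpartition("_")
    if muscle not in EMG_MUSCLES or tag not in ("L", "R"):
        raise ValueError(f"malformed EMG channel label {label!r}")
    return muscle, "left" if tag == "L" else "right"


@dataclass
class TrajectoryTrial:
    """Uniformly sampled 3D body-point positions for one walkway pass.

    ``points`` maps a body-point name to an ``(n, 3)`` array of positions in
    metres on the shared time base ``time`` (seconds).
    """

    time: np.ndarray
    points: dict[str, np.ndarray]
    sampling_rate: float
    walkway_length: float = 10.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("trial needs at least two time samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
            raise ValueError("sampling must be uniform with no missing samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.walkway_length <= 0:
            raise ValueError("walkway_length must be positive")
        clean = {}
        for name, arr in self.points.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.time.size, 3):
                raise ValueError(
                    f"body point {name!r} has shape {arr.shape}, expected "
                    f"{(self.time.size, 3)}"
                )
            clean[name] = arr
        self.points = clean

    def point(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingBodyPointError(
                f"body point {name!r} missing from trial (have {sorted(self.points)})"
            ) from None

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class GaitEventSet:
    """Ordered foot-contact and foot-off times (seconds) per side.

    Within a side contacts are strictly increasing and exactly one foot off
    lies between consecutive contacts; a leading or trailing foot off at the
    trial edges is permitted.
    """

    contacts: dict[str, np.ndarray]
    offs: dict[str, np.ndarray]
    source: str = "estimated"

    def __post_init__(self) -> None:
        if self.source not in ("truth", "estimated"):
            raise ValueError("source must be 'truth' or 'estimated'")
        self.contacts = {s: np.asarray(self.contacts.get(s, []), dtype=float) for s in SIDES}
        self.offs = {s: np.asarray(self.offs.get(s, []), dtype=float) for s in SIDES}
        self.validate()

    def validate(self) -> None:
        for side in SIDES:
            c, o = self.contacts[side], self.offs[side]
            if np.any(np.diff(c) <= 0):
                raise ValueError(f"{side} contacts not strictly increasing: {c}")
            if np.any(np.diff(o) <= 0):
                raise ValueError(f"{side} foot offs not strictly increasing: {o}")
            for lo, hi in zip(c[:-1], c[1:]):
                k = int(np.sum((o > lo) & (o < hi)))
                if k != 1:
                    raise ValueError(
                        f"{side}: expected exactly one foot off between contacts "
                        f"{lo:.3f}s and {hi:.3f}s, found {k}"
                    )

    def pooled_contacts(self) -> np.ndarray:
        """All foot contacts of both sides, sorted in time."""
        return np.sort(np.concatenate([self.contacts[s] for s in SIDES]))

    def shifted(self, dt: float) -> "GaitEventSet":
        return GaitEventSet(
            contacts={s: self.contacts[s] + dt for s in SIDES},
            offs={s: self.offs[s] + dt for s in SIDES},
            source=self.source,
        )

    def strides(self, side: str) -> list[tuple[float, float]]:
        """Complete contact-to-next-contact intervals of one side."""
        c = self.contacts[side]
        return [(float(a), float(b)) for a, b in zip(c[:-1], c[1:])]


@dataclass
class EmgRecording:
    """Multi-channel surface EMG on a uniform time base shared with the events.

    ``data`` columns are channel labels like ``TA_L``; values are in arbitrary
    analog units.
    """

    sampling_rate: float
    data: pd.DataFrame
    time: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.data) != self.time.size:
            raise ValueError("data and time lengths differ")
        labels = list(self.data.columns)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate channel labels")
        for lab in labels:
            parse_channel_label(lab)  # raises on unsupported muscles

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def channel(self, label: str) -> np.ndarray:
        if label not in self.data.columns:
            raise KeyError(f"channel {label!r} not recorded (have {self.channels})")
        return self.data[label].to_numpy()


__all__ = [
    "SIDES",
    "EMG_MUSCLES",
    "STIM_MUSCLES",
    "BODY_POINTS",
    "MissingBodyPointError",
    "InsufficientStridesError",
    "other_side",
    "ankle_point",
    "channel_label",
    "parse_channel_label",
    "TrajectoryTrial",
    "GaitEventSet",
    "EmgRecording",
]
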