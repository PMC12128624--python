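"""Gait-event detection from markerless trajectories.

Foot contacts are the local maxima, and foot offs the local minima, of each
ankle's anterior-posterior (AP) trajectory relative to the spine base.  The
relative signal is low-pass filtered (zero-lag) before the extremum search,
screened by prominence and minimum inter-contact interval, trimmed at the
recording edges, and finally forced to alternate contact/off per side.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import (
    SIDES,
    GaitEventSet,
    InsufficientStridesError,
    TrajectoryTrial,
    ankle_point,
    other_side,
)

log = logging.getLogger(__name__)


@dataclass
class EventDetectorConfig:
    """Tunables of the extremum-based detector.

    ``smoothing_hz``: zero-lag low-pass cut-off applied to the relative AP
    signal before the peak search (the 30 Hz markerless data are noisy).
    ``min_prominence_cm``: minimum peak prominence; rejects jitter extrema.
    ``cadence_max_spm``: upper cadence bound; sets the minimum inter-contact
    interval ``60 / (2 * cadence_max)`` seconds.
    ``edge_margin_strides``: extrema closer than this many (median) strides
    to a recording boundary are discarded as incomplete.
    """

    smoothing_hz: float = 6.0
    min_prominence_cm: float = 5.0
    cadence_max_spm: float = 180.0
    edge_margin_strides: float = 0.5
    refine_subsample: bool = True


def relative_ap_trajectory(trial: TrajectoryTrial, side: str) -> np.ndarray:
    """Ankle AP position minus spine-base AP position, on the trial time base."""
    ankle = trial.point(ankle_point(side))
    spine = trial.point("spine_base")
    return ankle[:, 0] - spine[:, 0]


def _smooth(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    if cutoff_hz <= 0 or cutoff_hz >= fs / 2:
        return x
    sos = signal.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _refine_peak(x: np.ndarray, i: int) -> float:
    """Sub-sample peak index by parabolic interpolation around sample ``i``."""
    if i <= 0 or i >= x.size - 1:
        return float(i)
    denom = x[i - 1] - 2 * x[i] + x[i + 1]
    if denom == 0:
        return float(i)
    delta = 0.5 * (x[i - 1] - x[i + 1]) / denom
    return float(i) + float(np.clip(delta, -0.5, 0.5))


def _extrema_times(
    x: np.ndarray, fs: float, config: EventDetectorConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Times of screened maxima and minima of ``x`` (ties -> earlier sample)."""
    prom = config.min_prominence_cm / 100.0
    dist = max(1, int(round(fs * 60.0 / (2.0 * config.cadence_max_spm))))
    out = []
    for sgn in (1.0, -1.0):
        idx, props = signal.find_peaks(
            sgn * x, prominence=prom, distance=dist, plateau_size=(1, None)
        )
        # resolve flat extrema to the earlier sample
        idx = np.where(props["plateau_sizes"] > 1, props["left_edges"], idx)
        if config.refine_subsample:
            times = np.array([_refine_peak(sgn * x, int(i)) for i in idx]) / fs
        else:
            times = idx / fs
        out.append(times)
    return out[0], out[1]


def detect_events(
    trial: TrajectoryTrial, config: EventDetectorConfig | None = None
) -> GaitEventSet:
    """Estimate foot contacts and foot offs for both sides.

    Raises :class:`InsufficientStridesError` when fewer than two valid
    contacts remain on a side after screening.
    """
    config = config or EventDetectorConfig()
    fs = trial.sampling_rate
    t0, t_end = float(trial.time[0]), float(trial.time[-1])

    contacts, offs = {}, {}
    for side in SIDES:
        rel = relative_ap_trajectory(trial, side)
        sm = _smooth(rel, fs, config.smoothing_hz)
        maxima, minima = _extrema_times(sm, fs, config)
        maxima += t0
        minima += t0

        if maxima.size >= 2:
            stride = float(np.median(np.diff(maxima)))
            margin = config.edge_margin_strides * stride
            maxima = maxima[(maxima - t0 >= margin) & (t_end - maxima >= margin)]
            minima = minima[(minima - t0 >= margin) & (t_end - minima >= margin)]
        if maxima.size < 2:
            raise InsufficientStridesError(
                f"insufficient strides: {maxima.size} foot contact(s) detected "
                f"on the {side} side"
            )

        # alternation: keep exactly one foot off between consecutive contacts
        kept = []
        sm_at = lambda tt: np.interp(tt, trial.time, sm)
        for lo, hi in zip(maxima[:-1], maxima[1:]):
            inside = minima[(minima > lo) & (minima < hi)]
            if inside.size == 0:
                continue
            if inside.size > 1:
                inside = inside[[int(np.argmin(sm_at(inside)))]]
            kept.append(float(inside[0]))
        contacts[side] = maxima
        offs[side] = np.array(kept)

    return GaitEventSet(contacts=contacts, offs=offs, source="estimated")


def single_support_intervals(
    events: GaitEventSet, side: str, atol: float = 1e-9
) -> list[tuple[float, float]]:
    """Single-support windows of ``side``: contralateral foot off to the next
    contralateral foot contact, restricted to intervals that lie inside a
    stance phase of ``side``.  Partial intervals at the trial edges are
    dropped.
    """
    contra = other_side(side)
    own_c = events.contacts[side]
    own_o = events.offs[side]
    out: list[tuple[float, float]] = []
    for f in events.offs[contra]:
        nxt = events.contacts[contra][events.contacts[contra] > f]
        if nxt.size == 0:
            continue  # partial interval at the trial end
        cc = float(nxt[0])
        # the supporting stance: last own contact before the contralateral off
        prev_c = own_c[own_c <= f + atol]
        if prev_c.size == 0:
            continue
        c = float(prev_c[-1])
        next_o = own_o[own_o > c]
        if next_o.size == 0:
            continue
        o = float(next_o[0])
        if cc > o + atol:
            raise ValueError(
                f"inconsistent event ordering: contralateral contact at {cc:.3f}s "
                f"falls after the {side} foot off at {o:.3f}s of the supporting "
                f"stance starting {c:.3f}s"
            )
        out.append((float(f), cc))
    for (a0, b0), (a1, b1) in zip(out[:-1], out[1:]):
        if a1 < b0 - atol:
            raise ValueError(
                f"overlapping single-support intervals ({a0:.3f},{b0:.3f}) and "
                f"({a1:.3f},{b1:.3f})"
            )
    return out


__all__ = [
    "EventDetectorConfig",
    "relative_ap_trajectory",
    "detect_events",
    "single_support_intervals",
]
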