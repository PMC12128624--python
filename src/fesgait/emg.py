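"""Surface-EMG envelope pipeline and the stimulated/non-stimulated ratio.

Processing chain, applied per channel in order: zero-phase Butterworth
high-pass at 20 Hz, zero-phase band-stop notches at the 50 Hz powerline
harmonics (k = 1..5), rectification as the modulus of the analytic signal
(Hilbert transform), and a zero-phase Butterworth low-pass at 5 Hz.  The
envelope is then segmented into strides at ipsilateral foot contacts,
resampled to a fixed 0-100% gait-cycle grid, screened for artefacts, and
peak-normalized per muscle.  The ratio statistic compares mean normalized
activity inside versus outside the gait-cycle window in which a muscle was
stimulated during training.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.fft import next_fast_len

from .core import (
    EmgRecording,
    GaitEventSet,
    InsufficientStridesError,
    parse_channel_label,
)

log = logging.getLogger(__name__)

#: Points of the normalized 0-100% gait-cycle grid.
N_CYCLE_POINTS = 101

#: Denominator guard for the stimulated/non-stimulated ratio.
RATIO_EPS = 1e-6


@dataclass
class FilterSpec:
    """EMG filter chain parameters.

    ``order`` is the net (bidirectional) Butterworth order: filters are
    designed at ``order // 2`` and applied forward-backward, giving a
    zero-phase response of the stated total order.  ``notch_bandwidth_hz``
    is the full width of each harmonic band-stop.
    """

    highpass_hz: float = 20.0
    lowpass_hz: float = 5.0
    notch_base_hz: float = 50.0
    notch_harmonics: int = 5
    order: int = 4
    bidirectional: bool = True
    notch_bandwidth_hz: float = 2.0

    def __post_init__(self) -> None:
        for name in ("highpass_hz", "lowpass_hz", "notch_base_hz",
                     "notch_bandwidth_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be an even integer >= 2")
        if self.notch_harmonics < 1:
            raise ValueError("notch_harmonics must be >= 1")

    def highest_notch_hz(self) -> float:
        return self.notch_base_hz * self.notch_harmonics


def _filtfilt(b: np.ndarray, a: np.ndarray, x: np.ndarray) -> np.ndarray:
    # Gustafsson edge handling makes forward-backward filtering exactly
    # time-reversal symmetric; irlen bounds the cost on long recordings.
    irlen = 3000 if x.size > 9000 else None
    return signal.filtfilt(b, a, x, method="gust", irlen=irlen)


def highpass(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    b, a = signal.butter(spec.order // 2, spec.highpass_hz, btype="highpass",
                         fs=fs)
    return _filtfilt(b, a, x)


def notch_harmonics(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    half = spec.notch_bandwidth_hz / 2.0
    for k in range(1, spec.notch_harmonics + 1):
        f0 = spec.notch_base_hz * k
        b, a = signal.butter(spec.order // 2, [f0 - half, f0 + half],
                             btype="bandstop", fs=fs)
        x = _filtfilt(b, a, x)
    return x


def rectify(x: np.ndarray) -> np.ndarray:
    """Modulus of the analytic signal (Hilbert-transform rectification)."""
    n = x.size
    analytic = signal.hilbert(x, N=next_fast_len(n))[:n]
    return np.abs(analytic)


def lowpass(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    b, a = signal.butter(spec.order // 2, spec.lowpass_hz, btype="lowpass",
                         fs=fs)
    return _filtfilt(b, a, x)


def filter_chain(
    recording: EmgRecording, spec: FilterSpec | None = None
) -> EmgRecording:
    """Apply the full processing chain to every channel; output is the
    non-negative linear envelope (small filter-ringing negatives clamped)."""
    spec = spec or FilterSpec()
    fs = recording.sampling_rate
    if fs <= 2 * spec.highest_notch_hz():
        raise ValueError(
            f"sampling rate {fs} Hz too low for notch filtering up to "
            f"{spec.highest_notch_hz()} Hz"
        )
    out = {}
    for label in recording.channels:
        x = recording.channel(label)
        x = highpass(x, fs, spec)
        x = notch_harmonics(x, fs, spec)
        x = rectify(x)
        x = lowpass(x, fs, spec)
        n_neg = int(np.sum(x < 0))
        if n_neg:
            log.debug("channel %s: clamped %d negative envelope samples",
                      label, n_neg)
            x = np.maximum(x, 0.0)
        out[label] = x
    return EmgRecording(sampling_rate=fs,
                        data=pd.DataFrame(out, index=recording.data.index),
                        time=recording.time)


def segment_strides(
    x: np.ndarray,
    time: np.ndarray,
    events: GaitEventSet,
    side: str,
    n_points: int = N_CYCLE_POINTS,
) -> np.ndarray:
    """Resample ``x`` to an ``(n_strides, n_points)`` gait-cycle matrix.

    Strides run from one ipsilateral foot contact to the next; strides that
    extend beyond the recorded signal are excluded.
    """
    strides = events.strides(side)
    t0, t1 = float(time[0]), float(time[-1])
    rows = []
    for (a, b) in strides:
        if a < t0 or b > t1:
            continue
        grid = np.linspace(a, b, n_points)
        rows.append(np.interp(grid, time, x))
    if not rows:
        raise InsufficientStridesError(
            f"no complete {side} stride inside the recorded signal"
        )
    return np.vstack(rows)


@dataclass
class ScreenRules:
    """Automated artefact screening (a surrogate for visual inspection).

    A stride is excluded when its RMS robust z-score (median / scaled MAD
    across strides) exceeds ``rms_z_max``, when it is a flatline
    (variance below ``flatline_var``), or when at least ``clip_run``
    consecutive samples sit at or above ``clip_fraction`` of ``adc_range``
    (clipping; inactive when ``adc_range`` is None).
    """

    rms_z_max: float = 4.0
    flatline_var: float = 1e-12
    clip_fraction: float = 0.99
    clip_run: int = 5
    adc_range: float | None = None


def _max_run_at_level(row: np.ndarray, level: float) -> int:
    hit = np.abs(row) >= level
    best = run = 0
    for h in hit:
        run = run + 1 if h else 0
        best = max(best, run)
    return best


def screen_artifacts(
    matrix: np.ndarray,
    rules: ScreenRules | None = None,
    manual_exclude: tuple[int, ...] = (),
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Drop artefact strides; returns the kept matrix and (index, reason) list."""
    rules = rules or ScreenRules()
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty stride matrix")
    n = matrix.shape[0]
    excluded: list[tuple[int, str]] = []
    rms = np.sqrt(np.mean(matrix**2, axis=1))
    med = np.median(rms)
    mad = np.median(np.abs(rms - med))
    z = (rms - med) / (1.4826 * mad + 1e-12)
    for i in range(n):
        if i in manual_exclude:
            excluded.append((i, "manual"))
        elif np.var(matrix[i]) < rules.flatline_var:
            excluded.append((i, "flatline"))
        elif z[i] > rules.rms_z_max:
            excluded.append((i, f"rms z={z[i]:.1f}"))
        elif rules.adc_range is not None and _max_run_at_level(
            matrix[i], rules.clip_fraction * rules.adc_range
        ) >= rules.clip_run:
            excluded.append((i, "clipping"))
    keep = [i for i in range(n) if i not in {j for j, _ in excluded}]
    if not keep:
        raise ValueError("no usable strides: every stride was excluded")
    return matrix[keep], excluded


def peak_normalize(matrix: np.ndarray) -> np.ndarray:
    """Divide by the muscle's peak over the assessment; the max becomes 1."""
    matrix = np.asarray(matrix, dtype=float)
    peak = matrix.max()
    if peak <= 0:
        raise ValueError("silent channel: peak EMG is not positive")
    return matrix / peak


@dataclass
class EmgEnvelope:
    """Processed, stride-normalized envelope of one channel."""

    muscle: str
    side: str
    stride_matrix: np.ndarray          # n_kept x N_CYCLE_POINTS, in [0, 1]
    excluded_strides: list[tuple[int, str]] = field(default_factory=list)

    def mean_profile(self) -> np.ndarray:
        return self.stride_matrix.mean(axis=0)


@dataclass
class StimRatio:
    muscle: str
    side: str
    ratio: float
    mean_stim: float
    mean_nonstim: float
    eps_guard_triggered: bool = False
    assessment: str | None = None

    def to_dict(self) -> dict:
        return {
            "muscle": self.muscle, "side": self.side, "ratio": self.ratio,
            "mean_stim": self.mean_stim, "mean_nonstim": self.mean_nonstim,
            "eps_guard_triggered": self.eps_guard_triggered,
            "assessment": self.assessment,
        }


def process_channel(
    recording: EmgRecording,
    label: str,
    events: GaitEventSet,
    spec: FilterSpec | None = None,
    rules: ScreenRules | None = None,
    manual_exclude: tuple[int, ...] = (),
) -> EmgEnvelope:
    """Full per-channel pipeline: filter, segment, screen, peak-normalize."""
    muscle, side = parse_channel_label(label)
    processed = filter_chain(
        EmgRecording(recording.sampling_rate, recording.data[[label]],
                     recording.time),
        spec,
    )
    matrix = segment_strides(processed.channel(label), processed.time,
                             events, side)
    kept, excluded = screen_artifacts(matrix, rules, manual_exclude)
    return EmgEnvelope(muscle=muscle, side=side,
                       stride_matrix=peak_normalize(kept),
                       excluded_strides=excluded)


def stim_ratio(
    envelope: EmgEnvelope | np.ndarray,
    stim_windows: list[tuple[float, float]],
    eps: float = RATIO_EPS,
    assessment: str | None = None,
    muscle: str = "",
    side: str = "",
) -> StimRatio:
    """Mean stride-averaged activity inside the stimulation window(s) over the
    mean outside.  ``stim_windows`` are closed gait-cycle fraction intervals;
    a wrapped window is passed as two intervals.
    """
    if isinstance(envelope, EmgEnvelope):
        profile = envelope.mean_profile()
        muscle, side = envelope.muscle, envelope.side
    else:
        profile = np.asarray(envelope, dtype=float)
    for (a, b) in stim_windows:
        if not (0 <= a < 1 and a < b <= 1):
            raise ValueError(
                f"stimulation window ({a}, {b}) outside the gait cycle [0, 1)"
            )
    phase = np.linspace(0.0, 1.0, profile.size)
    inside = np.zeros(profile.size, dtype=bool)
    for (a, b) in stim_windows:
        inside |= (phase >= a) & (phase <= b)
    if not inside.any() or inside.all():
        raise ValueError("stimulated and non-stimulated periods must both be non-empty")
    mean_stim = float(profile[inside].mean())
    mean_nonstim = float(profile[~inside].mean())
    guarded = mean_nonstim < eps
    ratio = mean_stim / max(mean_nonstim, eps)
    if guarded:
        log.warning("%s %s: non-stimulated mean below eps=%g; ratio guarded",
                    muscle, side, eps)
    return StimRatio(muscle=muscle, side=side, ratio=float(ratio),
                     mean_stim=mean_stim, mean_nonstim=mean_nonstim,
                     eps_guard_triggered=bool(guarded), assessment=assessment)


def ratio_change(ratios: list[StimRatio]) -> pd.DataFrame:
    """Signed changes vs baseline per muscle/side; missing assessments -> NaN.

    Input ratios must carry assessment labels from
    {baseline, post, followup}.
    """
    df = pd.DataFrame([r.to_dict() for r in ratios])
    if df.empty or df["assessment"].isna().any():
        raise ValueError("every ratio needs an assessment label")
    wide = df.pivot_table(index=["muscle", "side"], columns="assessment",
                          values="ratio", aggfunc="first")
    out = pd.DataFrame(index=wide.index)
    base = wide.get("baseline")
    if base is None:
        raise ValueError("no baseline assessment present")
    for label, col in (("post", "change_post"), ("followup", "change_followup")):
        out[col] = (wide[label] - base) if label in wide else np.nan
    n_other = sum(1 for lab in ("post", "followup") if lab in wide)
    if n_other < 1:
        raise ValueError("need at least two assessments sharing muscle/side")
    return out.reset_index()


__all__ = [
    "N_CYCLE_POINTS",
    "RATIO_EPS",
    "FilterSpec",
    "highpass",
    "notch_harmonics",
    "rectify",
    "lowpass",
    "filter_chain",
    "segment_strides",
    "ScreenRules",
    "screen_artifacts",
    "peak_normalize",
    "EmgEnvelope",
    "StimRatio",
    "process_channel",
    "stim_ratio",
    "ratio_change",
]
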