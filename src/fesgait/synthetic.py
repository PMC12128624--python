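"""Synthetic overground-gait generator with exact ground truth.

Produces 30 Hz body-point trajectories (left/right ankle, spine base),
1000 Hz multi-channel surface EMG, ground-truth gait events, and the
realized stimulation timeline for a periodic walkway pass.  The kinematic
construction is built so that the anterior-posterior (AP) ankle trajectory
relative to the spine base has exactly one maximum per stride at foot
contact and one minimum at foot off, and so that the ankle is exactly
stationary (up to the shared spine-speed modulation) during its
single-support window — the two properties the downstream event detector
and step-location estimator rely on.

Construction sketch, per side, with stride time ``T`` and stride length
``S = v*T``.  Let ``u`` be the within-stride phase (contact at ``u=0``,
foot off at ``u=SF``), and ``[SS0, SS1]`` the single-support phase window
(contralateral foot off to contralateral contact).  The ankle AP position
against a *linear* spine ``v*t`` is:

* ``u in [0, SS0]``   — Hermite bump ``P_k + S*SS0*w(1-w)^2`` landing on the
  footfall ``P_k`` with zero relative-AP slope at contact;
* ``u in [SS0, SS1]`` — exactly ``P_k`` (foot flat in single support);
* ``u in [SS1, SF]``  — Hermite dip ``P_k + S*(SF-SS1)*w^2(w-1)`` reaching
  the relative-AP minimum exactly at foot off;
* ``u in [SF, 1]``    — monotone swing ``P_k + S*sigma(w)`` to ``P_{k+1}``.

A smooth within-stride speed modulation (period ``T/2``) is added to both
the spine and the ankles, so it cancels in the relative signal.  Left/right
step-length asymmetry is realized by offsetting the contralateral contact
phase from 0.5, which leaves the waveform shape identical on both sides.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    EMG_MUSCLES,
    SIDES,
    EmgRecording,
    GaitEventSet,
    TrajectoryTrial,
    ankle_point,
    channel_label,
    other_side,
)

log = logging.getLogger(__name__)

#: Relative tolerance for the speed = step_length x cadence consistency check.
CONSISTENCY_RTOL = 0.05

#: Minimum double-support fraction required by the kinematic construction.
MIN_DOUBLE_SUPPORT = 0.02


@dataclass
class GaitProfile:
    """Parameters of one synthetic walkway pass.

    walking_speed in m/s; step length/width in cm; cadence in steps/min;
    ``step_length_asymmetry`` is right minus left step length in cm.
    ``walking_speed`` must be consistent with
    ``step_length_mean * cadence`` within :data:`CONSISTENCY_RTOL`.
    """

    walking_speed: float = 0.8
    step_length_mean: float = 48.0
    step_length_asymmetry: float = 0.0
    step_width_mean: float = 12.0
    cadence: float = 100.0
    stance_fraction: float = 0.62
    trajectory_rate: float = 30.0
    emg_rate: float = 1000.0
    walkway_length: float = 10.0
    noise_sd_trajectory: float = 0.3
    noise_sd_emg: float = 0.05
    powerline_amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walking_speed <= 0:
            raise ValueError("walking_speed must be positive")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must lie in (0, 1)")
        for name in ("cadence", "trajectory_rate", "emg_rate", "walkway_length",
                     "step_length_mean", "step_width_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("noise_sd_trajectory", "noise_sd_emg", "powerline_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        implied = self.step_length_mean / 100.0 * self.cadence / 60.0
        if abs(implied - self.walking_speed) > CONSISTENCY_RTOL * self.walking_speed:
            raise ValueError(
                "inconsistent profile: step_length_mean x cadence implies "
                f"{implied:.3f} m/s but walking_speed is {self.walking_speed:.3f} m/s "
                f"(tolerance {CONSISTENCY_RTOL:.0%})"
            )
        if abs(self.contact_offset) > 0.2:
            raise ValueError(
                "step_length_asymmetry too large for the stride length: the "
                "contralateral contact phase offset exceeds 0.2 strides"
            )
        if self.stance_fraction - 0.5 - abs(self.contact_offset) < MIN_DOUBLE_SUPPORT:
            raise ValueError(
                "stance_fraction leaves no double support: require "
                f"stance_fraction > 0.5 + |offset| + {MIN_DOUBLE_SUPPORT}"
            )

    # -- derived timing ----------------------------------------------------
    @property
    def stride_time(self) -> float:
        """Seconds per stride (two steps)."""
        return 120.0 / self.cadence

    @property
    def stride_length(self) -> float:
        """Metres per stride as actually constructed (speed x stride time)."""
        return self.walking_speed * self.stride_time

    @property
    def contact_offset(self) -> float:
        """Offset of the left contact phase from 0.5 (stride fractions).

        Negative offset places the left contact earlier, lengthening the
        right step; chosen so right minus left step length equals
        ``step_length_asymmetry``.
        """
        return -(self.step_length_asymmetry / 100.0) / (2.0 * self.stride_length)

    @property
    def duration(self) -> float:
        """Trial duration (s): time for the spine base to clear the walkway."""
        return (self.walkway_length + 0.1) / self.walking_speed

    def single_support_phases(self, side: str) -> tuple[float, float]:
        """Phase window (stride fractions) of ``side``'s single support."""
        d = self.contact_offset if side == "right" else -self.contact_offset
        return self.stance_fraction + d - 0.5, 0.5 + d


@dataclass
class MuscleBurstSpec:
    """One gait-phase-locked activation burst for an EMG channel.

    ``burst_onset`` and ``burst_duration`` are fractions of that side's gait
    cycle (contact at 0); the burst envelope is a raised cosine and wraps
    across the cycle boundary when ``onset + duration > 1``.
    """

    muscle: str
    side: str
    burst_onset: float
    burst_duration: float
    burst_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.muscle not in EMG_MUSCLES:
            raise ValueError(
                f"unknown muscle {self.muscle!r}; expected one of {EMG_MUSCLES}"
            )
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if not 0 <= self.burst_onset < 1:
            raise ValueError("burst_onset must lie in [0, 1)")
        if not 0 < self.burst_duration <= 1:
            raise ValueError("burst_duration must lie in (0, 1]")
        if self.burst_amplitude < 0:
            raise ValueError("burst_amplitude must be non-negative")


def default_burst_specs() -> list[MuscleBurstSpec]:
    """Bilateral burst timings loosely following normal-gait activation phases."""
    timing = {
        "TA": (0.60, 0.45, 1.0),
        "GAM": (0.15, 0.35, 1.0),
        "SOL": (0.15, 0.35, 0.9),
        "PL": (0.10, 0.40, 0.7),
        "RF": (0.95, 0.20, 0.8),
        "VL": (0.95, 0.25, 1.0),
        "ST": (0.80, 0.30, 0.9),
    }
    return [
        MuscleBurstSpec(m, side, *timing[m])
        for m in EMG_MUSCLES
        for side in SIDES
    ]


@dataclass
class SyntheticTrial:
    """A fully specified synthetic walkway pass with all ground truth."""

    trajectories: TrajectoryTrial
    events_truth: GaitEventSet
    emg: EmgRecording
    stim_truth: object  # StimulationTimeline; typed loosely to avoid a cycle
    profile: GaitProfile
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def _swing_sigma(w: np.ndarray, h: float) -> np.ndarray:
    # Cubic Hermite 0->1 with endpoint slope h (= 1 - stance_fraction), which
    # makes the relative-AP slope exactly zero at foot off and contact.
    return 3 * w**2 - 2 * w**3 + h * w * (1 - w) * (1 - 2 * w)


def _ankle_ap_linear(t: np.ndarray, profile: GaitProfile, side: str,
                     first_contact: float) -> np.ndarray:
    """Ankle AP position against a linear spine ``v*t`` (no modulation)."""
    T = profile.stride_time
    S = profile.stride_length
    sf = profile.stance_fraction
    ss0, ss1 = profile.single_support_phases(side)
    a0 = profile.step_length_mean / 200.0  # footfall lead over the spine (m)

    k = np.floor((t - first_contact) / T)
    u = (t - first_contact) / T - k
    tc = first_contact + k * T
    p = profile.walking_speed * tc + a0  # footfall positions P_k

    out = np.empty_like(t, dtype=float)

    m = u < ss0
    w = u[m] / ss0
    out[m] = p[m] + S * ss0 * w * (1 - w) ** 2

    m = (u >= ss0) & (u < ss1)
    out[m] = p[m]

    m = (u >= ss1) & (u < sf)
    w = (u[m] - ss1) / (sf - ss1)
    out[m] = p[m] + S * (sf - ss1) * w**2 * (w - 1)

    m = u >= sf
    w = (u[m] - sf) / (1 - sf)
    out[m] = p[m] + S * _swing_sigma(w, 1 - sf)

    return out


def _swing_lift(t: np.ndarray, profile: GaitProfile, first_contact: float) -> np.ndarray:
    """Vertical ankle lift during swing (m); zero in stance."""
    T = profile.stride_time
    sf = profile.stance_fraction
    u = np.mod((t - first_contact) / T, 1.0)
    lift = np.zeros_like(t, dtype=float)
    m = u >= sf
    w = (u[m] - sf) / (1 - sf)
    lift[m] = 0.05 * np.sin(np.pi * w) ** 2
    return lift


def _first_contacts(profile: GaitProfile) -> dict[str, float]:
    T = profile.stride_time
    right0 = 0.6 * T
    left0 = right0 + (0.5 + profile.contact_offset) * T
    return {"right": right0, "left": left0}


def generate_trajectories(
    profile: GaitProfile,
) -> tuple[TrajectoryTrial, GaitEventSet, dict]:
    """Generate one walkway pass: trajectories, ground-truth events, and truth.

    Returns ``(trial, events, truth)`` where ``truth`` holds the noiseless
    relative-AP signals, the constructed footfall locations (median ankle
    position over each single-support window, in cm), and the single-support
    windows — the oracles for the event detector and step-location estimator.
    """
    fs = profile.trajectory_rate
    T = profile.stride_time
    duration = profile.duration
    n = int(np.floor(duration * fs)) + 1
    t = np.arange(n) / fs
    t_end = t[-1]
    if t_end < 2.2 * T:
        raise ValueError("walkway too short to contain two full strides")

    rng = np.random.default_rng([int(profile.seed), 0])
    phase = rng.uniform(0, 2 * np.pi)
    v = profile.walking_speed
    mod = 0.005 * np.sin(4 * np.pi * t / T + phase)  # shared speed modulation
    spine_x = v * t + mod
    spine = np.column_stack([
        spine_x,
        0.01 * np.sin(2 * np.pi * t / T + phase),
        1.0 + 0.01 * np.sin(4 * np.pi * t / T + phase),
    ])

    first = _first_contacts(profile)
    half_w = profile.step_width_mean / 200.0
    points = {"spine_base": spine}
    relative = {}
    for side in SIDES:
        ap_lin = _ankle_ap_linear(t, profile, side, first[side])
        relative[side] = ap_lin - v * t
        y = np.full(n, half_w if side == "left" else -half_w)
        z = 0.09 + _swing_lift(t, profile, first[side])
        points[ankle_point(side)] = np.column_stack([ap_lin + mod, y, z])

    # ground-truth events: contacts at least 0.6 strides from either edge
    contacts, offs = {}, {}
    for side in SIDES:
        tc = first[side] + T * np.arange(0, int(np.ceil(t_end / T)) + 1)
        tc = tc[(tc >= 0.55 * T) & (tc <= t_end - 0.55 * T)]
        contacts[side] = tc
        fo = tc + profile.stance_fraction * T
        offs[side] = fo[fo <= t_end]
    events = GaitEventSet(contacts=contacts, offs=offs, source="truth")

    # truth footfalls: median noiseless ankle position over single support
    footfalls = {s: [] for s in SIDES}
    single_support = {s: [] for s in SIDES}
    for side in SIDES:
        ss0, ss1 = profile.single_support_phases(side)
        ap_lin = _ankle_ap_linear(t, profile, side, first[side])
        ml = points[ankle_point(side)][:, 1]
        contra = other_side(side)
        for c in contacts[side]:
            w0, w1 = c + ss0 * T, c + ss1 * T
            if w0 < 0 or w1 > t_end:
                continue
            # keep only windows bounded by emitted contralateral events
            if not (np.any(np.abs(offs[contra] - w0) < 1e-6)
                    and np.any(np.abs(contacts[contra] - w1) < 1e-6)):
                continue
            m = (t >= w0) & (t <= w1)
            single_support[side].append((w0, w1))
            footfalls[side].append({
                "t_start": w0,
                "t_end": w1,
                "ap_cm": float(np.median(ap_lin[m] + mod[m]) * 100),
                "ml_cm": float(np.median(ml[m]) * 100),
            })

    if profile.noise_sd_trajectory > 0:
        sd = profile.noise_sd_trajectory / 100.0
        for name in points:
            points[name] = points[name] + rng.normal(0, sd, size=points[name].shape)

    trial = TrajectoryTrial(
        time=t, points=points, sampling_rate=fs,
        walkway_length=profile.walkway_length,
    )
    truth = {
        "relative_ap": relative,
        "footfalls": footfalls,
        "single_support": single_support,
        "spine_modulation": mod,
    }
    return trial, events, truth


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def burst_envelope(phase: np.ndarray, bursts: list[MuscleBurstSpec]) -> np.ndarray:
    """Raised-cosine activation envelope at the given cycle phases in [0, 1)."""
    env = np.zeros_like(phase, dtype=float)
    for b in bursts:
        d = np.mod(phase - b.burst_onset, 1.0)
        m = d < b.burst_duration
        env[m] += b.burst_amplitude * 0.5 * (1 - np.cos(2 * np.pi * d[m] / b.burst_duration))
    return env


def generate_emg(
    profile: GaitProfile,
    bursts: list[MuscleBurstSpec],
    events: GaitEventSet,
) -> tuple[EmgRecording, dict[str, np.ndarray]]:
    """Synthesize gait-phase-locked EMG for every (muscle, side) with bursts.

    Each channel is the burst envelope multiplied by a zero-mean broadband
    carrier, plus powerline interference at 50 k Hz (k = 1..5, amplitude
    falling as 1/k, common random phase per trial) and additive white noise.
    Returns the recording and the per-channel ground-truth envelopes.
    """
    if all(events.contacts[s].size == 0 for s in SIDES):
        raise ValueError("events must contain at least one foot contact")
    for b in bursts:
        if events.contacts[b.side].size == 0:
            raise ValueError(f"no {b.side} contacts for burst on {b.muscle}")

    fs = profile.emg_rate
    n = int(np.floor(profile.duration * fs)) + 1
    t = np.arange(n) / fs
    T = profile.stride_time
    rng = np.random.default_rng([int(profile.seed), 1])
    powerline_phase = rng.uniform(0, 2 * np.pi)

    by_channel: dict[str, list[MuscleBurstSpec]] = {}
    for b in bursts:
        by_channel.setdefault(channel_label(b.muscle, b.side), []).append(b)

    powerline = np.zeros(n)
    if profile.powerline_amplitude > 0:
        for k in range(1, 6):
            powerline += (profile.powerline_amplitude / k) * np.sin(
                2 * np.pi * 50.0 * k * t + powerline_phase
            )

    data, truth_env = {}, {}
    for label in sorted(by_channel):
        chan_bursts = by_channel[label]
        side = chan_bursts[0].side
        c0 = events.contacts[side][0]
        phase = np.mod((t - c0) / T, 1.0)
        env = burst_envelope(phase, chan_bursts)
        carrier = rng.standard_normal(n)
        sig = env * carrier + powerline
        if profile.noise_sd_emg > 0:
            sig = sig + profile.noise_sd_emg * rng.standard_normal(n)
        data[label] = sig
        truth_env[label] = env

    rec = EmgRecording(sampling_rate=fs, data=pd.DataFrame(data), time=t)
    return rec, truth_env


# ---------------------------------------------------------------------------
# full trial + fixtures
# ---------------------------------------------------------------------------

def generate_trial(
    profile: GaitProfile,
    bursts: list[MuscleBurstSpec] | None = None,
) -> SyntheticTrial:
    """Generate trajectories, events, EMG, and the realized stimulation truth."""
    from .sequencer import default_schedule, realize_timeline

    if bursts is None:
        bursts = default_burst_specs()
    trial, events, truth = generate_trajectories(profile)
    emg, truth_env = generate_emg(profile, bursts, events)
    schedule = default_schedule(
        profile.stance_fraction, cycle_duration_ms=profile.stride_time * 1000.0
    )
    stim = realize_timeline(schedule, events)
    truth = dict(truth)
    truth["emg_envelopes"] = truth_env
    truth["schedule"] = schedule
    return SyntheticTrial(
        trajectories=trial,
        events_truth=events,
        emg=emg,
        stim_truth=stim,
        profile=profile,
        truth=truth,
    )


def write_fixture(trial: SyntheticTrial, directory) -> dict[str, str]:
    """Write a trial to CSV/JSON files that round-trip through the readers."""
    from pathlib import Path

    from . import io

    if trial.trajectories is None or trial.events_truth is None:
        raise ValueError("cannot write an empty trial")
    if all(trial.events_truth.contacts[s].size == 0 for s in SIDES):
        raise ValueError("cannot write a trial without any gait events")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectories": directory / "trajectories.csv",
        "events": directory / "events_truth.csv",
        "profile": directory / "profile.json",
    }
    io.write_trajectories_csv(trial.trajectories, paths["trajectories"])
    io.write_events_csv(trial.events_truth, paths["events"])
    io.write_profile_json(trial.profile, paths["profile"])
    if trial.emg is not None:
        paths["emg"] = directory / "emg.csv"
        io.write_emg_csv(trial.emg, paths["emg"])
    schedule = trial.truth.get("schedule")
    if schedule is not None:
        paths["schedule"] = directory / "schedule.json"
        io.write_schedule_json(schedule, paths["schedule"])
    return {k: str(v) for k, v in paths.items()}


def profile_to_dict(profile: GaitProfile) -> dict:
    return asdict(profile)


def recovery_trial_profiles(
    n_trials: int = 50,
    master_seed: int = 1,
    speed_range: tuple[float, float] = (0.2, 1.2),
    cadence_range: tuple[float, float] = (40.0, 130.0),
    noise_sd_trajectory: float = 0.5,
) -> list[GaitProfile]:
    """Seeded profiles spanning the slow-to-moderate gait envelope.

    Speeds and cadences are drawn uniformly over the given ranges, with the
    cadence range narrowed per draw so the implied step length stays within
    a plausible 15-90 cm; each profile gets its own deterministic seed.
    """
    rng = np.random.default_rng(int(master_seed))
    profiles = []
    for i in range(n_trials):
        v = rng.uniform(*speed_range)
        lo = max(cadence_range[0], 60.0 * v / 0.90)
        hi = min(cadence_range[1], 60.0 * v / 0.15)
        c = rng.uniform(lo, hi)
        profiles.append(GaitProfile(
            walking_speed=v,
            cadence=c,
            step_length_mean=v * 6000.0 / c,
            noise_sd_trajectory=noise_sd_trajectory,
            seed=int(master_seed) * 1000 + i,
        ))
    return profiles


__all__ = [
    "CONSISTENCY_RTOL",
    "GaitProfile",
    "MuscleBurstSpec",
    "SyntheticTrial",
    "default_burst_specs",
    "burst_envelope",
    "generate_trajectories",
    "generate_emg",
    "generate_trial",
    "write_fixture",
    "profile_to_dict",
    "recovery_trial_profiles",
]
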