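"""CSV/JSON readers and writers.

Formats (all plain text):

* ``trajectories.csv`` — ``time_s, point, x_m, y_m, z_m`` (long format).
* ``emg.csv`` — ``time_s`` plus one column per channel named ``<MUSCLE>_<L|R>``.
* ``events*.csv`` — ``side, event, time_s`` with event in
  ``{foot_contact, foot_off}``.
* ``profile.json`` — all gait-profile fields.
* ``schedule.json`` — stimulation channel specs plus the nominal cycle.
* session logs — CSV with the feasibility schema.

Everything written by the toolkit is readable by the toolkit.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BODY_POINTS, SIDES, EmgRecording, GaitEventSet, TrajectoryTrial
from .sequencer import StimulationChannelSpec, StimulationSchedule
from .synthetic import GaitProfile

SCHEMA_VERSION = "1.0"


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface the file (and pandas' line info)
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


# -- trajectories -----------------------------------------------------------

def write_trajectories_csv(trial: TrajectoryTrial, path) -> None:
    frames = []
    for name, arr in trial.points.items():
        frames.append(pd.DataFrame({
            "time_s": trial.time, "point": name,
            "x_m": arr[:, 0], "y_m": arr[:, 1], "z_m": arr[:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories_csv(
    path, sampling_rate: float | None = None, walkway_length: float = 10.0
) -> TrajectoryTrial:
    df = _read_csv(path, ["time_s", "point", "x_m", "y_m", "z_m"])
    points = {}
    time = None
    for name, grp in df.groupby("point"):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy()
        if time is None:
            time = t
        elif t.size != time.size or not np.allclose(t, time):
            raise ValueError(f"{path}: body points have differing time bases")
        points[name] = grp[["x_m", "y_m", "z_m"]].to_numpy()
    if time is None:
        raise ValueError(f"{path}: no trajectory rows")
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
    return TrajectoryTrial(time=time, points=points, sampling_rate=sampling_rate,
                           walkway_length=walkway_length)


# -- events -----------------------------------------------------------------

_EVENT_NAMES = {"foot_contact", "foot_off"}


def write_events_csv(events: GaitEventSet, path) -> None:
    rows = []
    for side in SIDES:
        for t in events.contacts[side]:
            rows.append({"side": side, "event": "foot_contact", "time_s": t})
        for t in events.offs[side]:
            rows.append({"side": side, "event": "foot_off", "time_s": t})
    pd.DataFrame(rows).sort_values("time_s").to_csv(path, index=False)


def read_events_csv(path, source: str = "truth") -> GaitEventSet:
    df = _read_csv(path, ["side", "event", "time_s"])
    bad = ~df["event"].isin(_EVENT_NAMES)
    if bad.any():
        raise ValueError(f"{path}: unknown events {sorted(df.loc[bad, 'event'].unique())}")
    contacts, offs = {}, {}
    for side in SIDES:
        sub = df[df["side"] == side]
        contacts[side] = np.sort(sub.loc[sub["event"] == "foot_contact", "time_s"].to_numpy())
        offs[side] = np.sort(sub.loc[sub["event"] == "foot_off", "time_s"].to_numpy())
    return GaitEventSet(contacts=contacts, offs=offs, source=source)


# -- EMG --------------------------------------------------------------------

def write_emg_csv(recording: EmgRecording, path) -> None:
    out = recording.data.copy()
    out.insert(0, "time_s", recording.time)
    out.to_csv(path, index=False)


def read_emg_csv(path, sampling_rate: float | None = None) -> EmgRecording:
    df = _read_csv(path, ["time_s"])
    time = df["time_s"].to_numpy()
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
    return EmgRecording(sampling_rate=sampling_rate,
                        data=df.drop(columns="time_s"), time=time)


# -- profile ----------------------------------------------------------------

def write_profile_json(profile: GaitProfile, path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(profile), indent=2, sort_keys=True) + "\n"
    )


def read_profile_json(path) -> GaitProfile:
    payload = json.loads(Path(path).read_text())
    fields = {f.name for f in dataclasses.fields(GaitProfile)}
    unknown = set(payload) - fields
    if unknown:
        raise ValueError(f"{path}: unknown profile fields {sorted(unknown)}")
    return GaitProfile(**payload)


# -- schedule ---------------------------------------------------------------

def write_schedule_json(schedule: StimulationSchedule, path) -> None:
    payload = {
        "cycle_duration_ms": schedule.cycle_duration_ms,
        "channels": [dataclasses.asdict(c) for c in schedule.channels],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_schedule_json(path) -> StimulationSchedule:
    payload = json.loads(Path(path).read_text())
    channels = [StimulationChannelSpec(**c) for c in payload["channels"]]
    return StimulationSchedule(channels=channels,
                               cycle_duration_ms=payload["cycle_duration_ms"])


# -- session log ------------------------------------------------------------

def write_session_log_csv(log_df: pd.DataFrame, path) -> None:
    log_df.to_csv(path, index=False)


def read_session_log_csv(path) -> pd.DataFrame:
    from .feasibility import SESSION_COLUMNS

    df = _read_csv(path, SESSION_COLUMNS)
    df["reason_missed"] = df["reason_missed"].fillna("")
    df["issue_resolved"] = df["issue_resolved"].fillna("")
    return df


# -- reports ----------------------------------------------------------------

def write_report_json(report: dict, path) -> None:
    report = dict(report)
    report.setdefault("schema_version", SCHEMA_VERSION)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report_json(path) -> dict:
    return json.loads(Path(path).read_text())


__all__ = [
    "SCHEMA_VERSION",
    "write_trajectories_csv", "read_trajectories_csv",
    "write_events_csv", "read_events_csv",
    "write_emg_csv", "read_emg_csv",
    "write_profile_json", "read_profile_json",
    "write_schedule_json", "read_schedule_json",
    "write_session_log_csv", "read_session_log_csv",
    "write_report_json", "read_report_json",
]
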