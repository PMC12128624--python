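"""Feasibility and safety metrics from training-session logs.

Adherence is the percentage of planned sessions attended; missed-session
statistics use the sample standard deviation (n-1 denominator).  Sessions
with unresolved technical issues that prevented stimulation are, by
default, reclassified as missed.  Questionnaire items are summarized as
medians on their declared ordinal scales.  The walked-distance series is
expressed as percent difference versus the first training session, with
missed or short (< 30 min) sessions linearly interpolated and flagged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ISSUE_CATEGORIES = ("none", "zipper", "imu", "connection")
RESOLUTION_LEVELS = ("yes", "no", "partial", "")

SESSION_COLUMNS = [
    "participant", "session", "attended", "reason_missed",
    "duration_min", "distance_m", "technical_issue", "issue_resolved",
]

#: Questionnaire items and their ordinal scale bounds.
QUESTIONNAIRE_SCALES: dict[str, tuple[int, int]] = {
    "satisfaction": (0, 10),
    "frequency": (1, 4),
    "duration": (1, 5),
    "comfort": (1, 5),
    "donning": (1, 5),
    "doffing": (1, 5),
    "helpfulness": (1, 5),
}

MIN_SESSION_MINUTES = 30.0


def validate_session_log(
    log_df: pd.DataFrame, reclassify_unresolved: bool = True
) -> pd.DataFrame:
    """Check the session-log schema; optionally reclassify sessions whose
    technical issue was not resolved as missed."""
    missing = [c for c in SESSION_COLUMNS if c not in log_df.columns]
    if missing:
        raise ValueError(f"session log missing columns: {missing}")
    df = log_df.copy()
    df["attended"] = df["attended"].map(
        {True: True, False: False, "yes": True, "no": False}
    )
    if df["attended"].isna().any():
        raise ValueError("attended must be yes/no")
    bad = ~df["technical_issue"].isin(ISSUE_CATEGORIES)
    if bad.any():
        raise ValueError(
            f"unknown technical_issue values: {sorted(df.loc[bad, 'technical_issue'].unique())}"
        )
    dup = df.duplicated(subset=["participant", "session"])
    if dup.any():
        raise ValueError("session index must be unique per participant")
    if (df.loc[~df["attended"], "duration_min"].fillna(0) > 0).any():
        raise ValueError("missed sessions must not record a duration")
    if reclassify_unresolved:
        unresolved = df["attended"] & (df["technical_issue"] != "none") & (
            df["issue_resolved"] == "no"
        )
        if unresolved.any():
            log.info("reclassifying %d session(s) with unresolved issues as missed",
                     int(unresolved.sum()))
            df.loc[unresolved, "attended"] = False
            df.loc[unresolved, "duration_min"] = np.nan
            df.loc[unresolved, "reason_missed"] = "unresolved technical issue"
    return df


def adherence(
    log_df: pd.DataFrame, planned_per_participant: int
) -> tuple[float, float, float | None]:
    """(adherence %, mean missed per participant, sample SD of missed).

    The SD is None when only one participant is logged.  Raises when any
    participant is missing planned session rows.
    """
    counts = log_df.groupby("participant")["session"].count()
    gaps = counts[counts != planned_per_participant]
    if not gaps.empty:
        raise ValueError(
            "participants with missing session rows (planned "
            f"{planned_per_participant}): {gaps.to_dict()}"
        )
    missed = (
        planned_per_participant
        - log_df.groupby("participant")["attended"].sum()
    ).to_numpy(dtype=float)
    total_planned = planned_per_participant * missed.size
    pct = 100.0 * (total_planned - missed.sum()) / total_planned
    sd = float(np.std(missed, ddof=1)) if missed.size > 1 else None
    return float(pct), float(missed.mean()), sd


def issue_summary(log_df: pd.DataFrame) -> dict:
    """Counts of sessions with each technical-issue category, their total,
    and a resolution breakdown."""
    issues = log_df[log_df["technical_issue"] != "none"]
    by_cat = {
        cat: int((issues["technical_issue"] == cat).sum())
        for cat in ISSUE_CATEGORIES if cat != "none"
    }
    resolution = {
        level: int((issues["issue_resolved"] == level).sum())
        for level in ("yes", "no", "partial")
    }
    return {
        "by_category": by_cat,
        "total": int(sum(by_cat.values())),
        "resolution": resolution,
    }


def questionnaire_medians(
    responses: pd.DataFrame,
    scales: dict[str, tuple[int, int]] | None = None,
) -> pd.Series:
    """Median response per item; responses outside the declared scale are
    rejected with the offending row."""
    scales = scales or QUESTIONNAIRE_SCALES
    for col in ("item", "participant", "response"):
        if col not in responses.columns:
            raise ValueError(f"responses table missing column {col!r}")
    for idx, row in responses.iterrows():
        item = row["item"]
        if item not in scales:
            raise ValueError(f"row {idx}: unknown questionnaire item {item!r}")
        lo, hi = scales[item]
        if not lo <= row["response"] <= hi:
            raise ValueError(
                f"row {idx}: response {row['response']} outside the "
                f"{lo}-{hi} scale of item {item!r}"
            )
    return responses.groupby("item")["response"].median()


def training_distance_series(
    log_df: pd.DataFrame, min_duration_min: float = MIN_SESSION_MINUTES
) -> pd.DataFrame:
    """Per-participant percent difference in walked distance vs session 1.

    Missed sessions and sessions shorter than ``min_duration_min`` get
    linearly interpolated values flagged ``interpolated``.
    """
    frames = []
    for pid, grp in log_df.sort_values("session").groupby("participant"):
        sessions = grp["session"].to_numpy()
        first = grp.iloc[0]
        valid = (
            grp["attended"].to_numpy(dtype=bool)
            & (grp["duration_min"].fillna(0).to_numpy() >= min_duration_min)
            & grp["distance_m"].notna().to_numpy()
        )
        if not valid[0]:
            raise ValueError(
                f"participant {pid}: first session missing or invalid; the "
                "distance series needs a recorded first session"
            )
        d0 = float(first["distance_m"])
        pct = np.full(sessions.size, np.nan)
        pct[valid] = 100.0 * (grp.loc[valid, "distance_m"].to_numpy() - d0) / d0
        pct[~valid] = np.interp(sessions[~valid], sessions[valid], pct[valid])
        frames.append(pd.DataFrame({
            "participant": pid,
            "session": sessions,
            "pct_diff": pct,
            "interpolated": ~valid,
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class FeasibilityReport:
    adherence_pct: float
    missed_mean: float
    missed_sd: float | None
    issue_counts: dict
    issue_total: int
    questionnaire_medians: dict = field(default_factory=dict)
    adverse_events: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "adherence_pct": self.adherence_pct,
            "missed_mean": self.missed_mean,
            "missed_sd": self.missed_sd,
            "issue_counts": self.issue_counts,
            "issue_total": self.issue_total,
            "questionnaire_medians": self.questionnaire_medians,
            "adverse_events": list(self.adverse_events),
        }


def feasibility_report(
    log_df: pd.DataFrame,
    planned_per_participant: int,
    questionnaire: pd.DataFrame | None = None,
    adverse_events: list | None = None,
    reclassify_unresolved: bool = True,
) -> FeasibilityReport:
    df = validate_session_log(log_df, reclassify_unresolved)
    pct, mean, sd = adherence(df, planned_per_participant)
    issues = issue_summary(df)
    medians = {}
    if questionnaire is not None:
        medians = questionnaire_medians(questionnaire).to_dict()
    return FeasibilityReport(
        adherence_pct=pct, missed_mean=mean, missed_sd=sd,
        issue_counts=issues["by_category"], issue_total=issues["total"],
        questionnaire_medians=medians, adverse_events=adverse_events or [],
    )


def make_session_log(
    missed_counts: dict[str, int] | list[int],
    planned_per_participant: int,
    issues: list[tuple[str, int, str, str]] | None = None,
    duration_min: float = 30.0,
    distance_m: float = 400.0,
) -> pd.DataFrame:
    """Construct a session log with given per-participant missed counts.

    ``issues`` is a list of (participant, session, category, resolved)
    annotations added to the corresponding rows.  Missed sessions are placed
    at the end of each participant's schedule.
    """
    if isinstance(missed_counts, list):
        missed_counts = {f"P{i + 1}": m for i, m in enumerate(missed_counts)}
    rows = []
    for pid, n_missed in missed_counts.items():
        if n_missed > planned_per_participant:
            raise ValueError(f"{pid}: missed count exceeds planned sessions")
        for s in range(1, planned_per_participant + 1):
            attended = s <= planned_per_participant - n_missed
            rows.append({
                "participant": pid,
                "session": s,
                "attended": "yes" if attended else "no",
                "reason_missed": "" if attended else "illness",
                "duration_min": duration_min if attended else np.nan,
                "distance_m": distance_m if attended else np.nan,
                "technical_issue": "none",
                "issue_resolved": "",
            })
    df = pd.DataFrame(rows)
    for (pid, session, category, resolved) in issues or []:
        m = (df["participant"] == pid) & (df["session"] == session)
        if not m.any():
            raise ValueError(f"no session {session} for participant {pid}")
        df.loc[m, "technical_issue"] = category
        df.loc[m, "issue_resolved"] = resolved
    return df


__all__ = [
    "ISSUE_CATEGORIES",
    "SESSION_COLUMNS",
    "QUESTIONNAIRE_SCALES",
    "MIN_SESSION_MINUTES",
    "validate_session_log",
    "adherence",
    "issue_summary",
    "questionnaire_medians",
    "training_distance_series",
    "FeasibilityReport",
    "feasibility_report",
    "make_session_log",
]
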