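"""Session segmentation by the one-hour inactivity rule, and session statistics.

A session is a maximal run of one user's events in which every gap between
consecutive events is below an inactivity threshold (60 minutes by default).
A gap equal to the threshold already starts a new session ("inactive for an
hour or more").  Both views and posts count as activity by default; a type
filter is available.

Single-event sessions have duration 0 and are included in all statistics.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GAP_THRESHOLD_MIN",
    "SESSION_COLUMNS",
    "SessionStats",
    "segment_sessions",
    "segment_all_sessions",
    "interevent_times",
    "session_duration_stats",
    "default_log_bins",
]

DEFAULT_GAP_THRESHOLD_MIN = 60.0
SESSION_COLUMNS = ["user_id", "start", "end", "n_events", "duration_min"]


def _check_sorted_single_user(events: pd.DataFrame) -> None:
    if events["user_id"].nunique() > 1:
        raise ValueError("events must all belong to a single user")
    if not events["timestamp"].is_monotonic_increasing:
        raise ValueError("events must be sorted by timestamp")


def _segment(events: pd.DataFrame, gap_threshold_min: float) -> pd.DataFrame:
    ts = events["timestamp"]
    gap_min = ts.diff().dt.total_seconds().div(60.0)
    new_session = gap_min.isna() | (gap_min >= gap_threshold_min) | (
        events["user_id"] != events["user_id"].shift()
    )
    sid = new_session.cumsum()
    grouped = events.groupby(sid)
    out = pd.DataFrame(
        {
            "user_id": grouped["user_id"].first(),
            "start": grouped["timestamp"].first(),
            "end": grouped["timestamp"].last(),
            "n_events": grouped.size(),
        }
    ).reset_index(drop=True)
    out["duration_min"] = (out["end"] - out["start"]).dt.total_seconds() / 60.0
    return out


def segment_sessions(
    events: pd.DataFrame,
    gap_threshold_min: float = DEFAULT_GAP_THRESHOLD_MIN,
    event_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Segment one user's sorted events into sessions.

    A new session starts at every event whose gap to the previous event is
    greater than or equal to ``gap_threshold_min`` minutes.  Returns one row
    per session with columns ``user_id, start, end, n_events, duration_min``,
    in chronological order; the sessions partition the input events.

    Raises ``ValueError`` on mixed user ids, unsorted input or a non-positive
    threshold.
    """
    if gap_threshold_min <= 0:
        raise ValueError("gap_threshold_min must be positive")
    if event_types is not None:
        events = events[events["event_type"].isin(set(event_types))]
    if events.empty:
        return pd.DataFrame(columns=SESSION_COLUMNS)
    _check_sorted_single_user(events)
    return _segment(events, gap_threshold_min)


def segment_all_sessions(
    events: pd.DataFrame,
    gap_threshold_min: float = DEFAULT_GAP_THRESHOLD_MIN,
    event_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Segment a full (multi-user) event log, user by user.

    The log must be sorted by ``(user_id, timestamp)`` as produced by
    :func:`forumdyn.event_log.read_event_log`.
    """
    if gap_threshold_min <= 0:
        raise ValueError("gap_threshold_min must be positive")
    if event_types is not None:
        events = events[events["event_type"].isin(set(event_types))]
    if events.empty:
        return pd.DataFrame(columns=SESSION_COLUMNS)
    by_user = events.groupby("user_id")["timestamp"]
    if (by_user.apply(lambda s: s.is_monotonic_increasing) == False).any():  # noqa: E712
        raise ValueError("events must be sorted by timestamp within each user")
    return _segment(events, gap_threshold_min)


def interevent_times(events: pd.DataFrame) -> np.ndarray:
    """Chronological gaps (minutes) between consecutive events of one user.

    Returns an empty array for fewer than two events; simultaneous events
    contribute a gap of 0.
    """
    if events.empty:
        return np.empty(0)
    _check_sorted_single_user(events)
    gaps = events["timestamp"].diff().dt.total_seconds().div(60.0).to_numpy()[1:]
    return gaps


def default_log_bins(n_bins: int = 40) -> np.ndarray:
    """Base-10 logarithmic bin edges from 1 minute to 60 days (in minutes)."""
    return np.logspace(0.0, np.log10(60.0 * 24.0 * 60.0), n_bins + 1)


@dataclasses.dataclass
class SessionStats:
    """Mean session duration, duration survival fractions and a log-binned
    inter-event-time histogram."""

    mean_duration: float
    survival_at: dict[float, float]
    interevent_histogram: tuple[np.ndarray, np.ndarray] | None = None

    def to_dict(self) -> dict:
        d: dict = {
            "mean_duration_min": self.mean_duration,
            "survival_at": {str(k): v for k, v in self.survival_at.items()},
        }
        if self.interevent_histogram is not None:
            counts, edges = self.interevent_histogram
            d["interevent_histogram"] = {
                "counts": counts.tolist(),
                "bin_edges_min": edges.tolist(),
            }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def session_duration_stats(
    sessions: pd.DataFrame,
    probe_points: Sequence[float] = (10.0, 60.0),
    interevent_minutes: np.ndarray | Iterable[float] | None = None,
    bins: np.ndarray | None = None,
) -> SessionStats:
    """Duration statistics over all sessions (zero-duration sessions included).

    ``survival_at[p]`` is the fraction of sessions lasting at least ``p``
    minutes.  If inter-event gaps are supplied they are histogrammed in
    base-10 logarithmic bins (1 minute to 60 days by default).
    """
    if sessions.empty:
        raise ValueError("no sessions to summarise")
    durations = sessions["duration_min"].to_numpy(dtype=float)
    survival = {float(p): float(np.mean(durations >= p)) for p in probe_points}
    hist = None
    if interevent_minutes is not None:
        gaps = np.asarray(list(interevent_minutes), dtype=float)
        edges = default_log_bins() if bins is None else np.asarray(bins, dtype=float)
        counts, edges = np.histogram(gaps, bins=edges)
        hist = (counts, edges)
    return SessionStats(
        mean_duration=float(durations.mean()),
        survival_at=survival,
        interevent_histogram=hist,
    )
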