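"""Event-log and category-table I/O, domain types, and descriptive statistics.

The canonical in-memory representation of an event log is a :class:`pandas.DataFrame`
with columns ``event_id, user_id, post_id, category_id, event_type, timestamp``,
sorted by ``(user_id, timestamp)`` with a stable order for ties.  ``timestamp`` is
timezone-aware UTC at second resolution.  An :class:`EventRecord` dataclass is
provided for typed access to single rows.

Categories carry a 10-level COPINE severity grade; grades 1-6 form the
``NonSexual`` segment and grades 7-10 the ``Sexual`` segment.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "VIEW",
    "POST",
    "EVENT_TYPES",
    "NON_SEXUAL",
    "SEXUAL",
    "SEGMENT_BOUNDARY_GRADE",
    "EVENT_COLUMNS",
    "CATEGORY_COLUMNS",
    "EventRecord",
    "DescriptiveSummary",
    "segment_for_grade",
    "read_event_log",
    "write_event_log",
    "events_from_records",
    "records_from_events",
    "read_categories",
    "write_categories",
    "descriptive_summary",
]

VIEW = "view"
POST = "post"
EVENT_TYPES = frozenset({VIEW, POST})

NON_SEXUAL = "NonSexual"
SEXUAL = "Sexual"
#: lowest COPINE grade belonging to the "Sexual" segment
SEGMENT_BOUNDARY_GRADE = 7

EVENT_COLUMNS = ["event_id", "user_id", "post_id", "category_id", "event_type", "timestamp"]
CATEGORY_COLUMNS = ["category_id", "label", "copine_grade"]

# ISO 8601 timestamps must carry an explicit UTC offset; naive times are rejected.
_TZ_SUFFIX = re.compile(r"(?:Z|[+-]\d{2}:?\d{2})$")


@dataclasses.dataclass(frozen=True)
class EventRecord:
    """One forum interaction (a view or a post) by a user on a post in a category."""

    event_id: int
    user_id: int
    post_id: int
    category_id: int
    event_type: str
    timestamp: pd.Timestamp

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        for field in ("event_id", "user_id", "post_id", "category_id"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be non-negative")
        ts = self.timestamp
        if ts.tzinfo is None:
            raise ValueError("timestamp must be timezone-aware (UTC)")


def segment_for_grade(copine_grade: int) -> str:
    """COPINE segment for a grade: ``NonSexual`` for 1-6, ``Sexual`` for 7-10."""
    grade = int(copine_grade)
    if not 1 <= grade <= 10:
        raise ValueError(f"copine_grade must be in 1..10, got {copine_grade}")
    return SEXUAL if grade >= SEGMENT_BOUNDARY_GRADE else NON_SEXUAL


def _sort_events(events: pd.DataFrame) -> pd.DataFrame:
    return events.sort_values(
        ["user_id", "timestamp"], kind="stable", ignore_index=True
    )


def read_event_log(path: str | Path) -> pd.DataFrame:
    """Read an event-log CSV.

    The file must have the header ``event_id,user_id,post_id,category_id,
    event_type,timestamp`` with ISO 8601 timestamps carrying an explicit UTC
    offset (e.g. ``2014-02-01T10:00:00Z``).  Records are returned sorted by
    ``(user_id, timestamp)``; ties keep file order.

    Raises
    ------
    ValueError
        On a missing/extra header, a malformed row (naming its line number),
        an unknown event type, or a timezone-naive timestamp.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != EVENT_COLUMNS:
        raise ValueError(
            f"expected columns {EVENT_COLUMNS}, got {list(df.columns)} in {path}"
        )
    if df.empty:
        out = df.copy()
        for col in ("event_id", "user_id", "post_id", "category_id"):
            out[col] = out[col].astype(np.int64)
        out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True)
        return out

    def _bad(mask: pd.Series, reason: str) -> None:
        if mask.any():
            # +2: one for the header line, one for 0- vs 1-based indexing
            line = int(mask.idxmax()) + 2
            raise ValueError(f"{reason} at line {line} of {path}")

    for col in ("event_id", "user_id", "post_id", "category_id"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        _bad(numeric.isna() | (numeric % 1 != 0), f"malformed integer in column {col!r}")
        _bad(numeric < 0, f"negative id in column {col!r}")
        df[col] = numeric.astype(np.int64)

    _bad(~df["event_type"].isin(EVENT_TYPES), "unknown event_type")
    _bad(~df["timestamp"].str.contains(_TZ_SUFFIX), "timezone-naive or malformed timestamp")
    parsed = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
    _bad(parsed.isna(), "unparseable timestamp")
    df["timestamp"] = parsed
    return _sort_events(df)


def write_event_log(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event log to CSV with ISO 8601 ``Z``-suffixed timestamps."""
    out = events.loc[:, EVENT_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def events_from_records(records: Iterable[EventRecord]) -> pd.DataFrame:
    """Build a sorted event-log frame from :class:`EventRecord` instances."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if df.empty:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
        return df
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return _sort_events(df)


def records_from_events(events: pd.DataFrame) -> list[EventRecord]:
    return [
        EventRecord(
            event_id=int(r.event_id),
            user_id=int(r.user_id),
            post_id=int(r.post_id),
            category_id=int(r.category_id),
            event_type=str(r.event_type),
            timestamp=pd.Timestamp(r.timestamp),
        )
        for r in events.itertuples(index=False)
    ]


def read_categories(path: str | Path) -> pd.DataFrame:
    """Read a category table CSV and derive the COPINE segment per category.

    Expects header ``category_id,label,copine_grade``; adds a ``segment``
    column (``NonSexual`` for grades 1-6, ``Sexual`` for 7-10).
    """
    df = pd.read_csv(path)
    if list(df.columns) != CATEGORY_COLUMNS:
        raise ValueError(
            f"expected columns {CATEGORY_COLUMNS}, got {list(df.columns)} in {path}"
        )
    df["category_id"] = df["category_id"].astype(np.int64)
    df["copine_grade"] = df["copine_grade"].astype(np.int64)
    bad = ~df["copine_grade"].between(1, 10)
    if bad.any():
        raise ValueError(
            f"copine_grade outside 1..10 at line {int(bad.idxmax()) + 2} of {path}"
        )
    df["segment"] = [segment_for_grade(g) for g in df["copine_grade"]]
    return df.sort_values("category_id", ignore_index=True)


def write_categories(categories: pd.DataFrame, path: str | Path) -> None:
    categories.loc[:, CATEGORY_COLUMNS].to_csv(path, index=False)


@dataclasses.dataclass
class DescriptiveSummary:
    """Corpus-level counts, per-user activity distributions and cumulative series.

    ``views_per_user`` etc. are indexed by ``user_id`` and cover only users with at
    least one event of the relevant type, so each distribution sums to its total.
    Cumulative series are indexed by UTC calendar day.
    """

    n_users: int
    n_posts: int
    n_views: int
    n_categories: int
    views_per_user: pd.Series
    posts_per_user: pd.Series
    unique_categories_viewed_per_user: pd.Series
    unique_categories_posted_per_user: pd.Series
    cumulative_daily_views: pd.Series
    cumulative_daily_posts: pd.Series

    def to_dict(self) -> dict:
        """JSON-serialisable summary (distributions reduced to moments)."""

        def _stats(s: pd.Series) -> dict:
            if len(s) == 0:
                return {"n": 0}
            return {
                "n": int(len(s)),
                "mean": float(s.mean()),
                "median": float(s.median()),
                "max": int(s.max()),
            }

        return {
            "n_users": self.n_users,
            "n_posts": self.n_posts,
            "n_views": self.n_views,
            "n_categories": self.n_categories,
            "views_per_user": _stats(self.views_per_user),
            "posts_per_user": _stats(self.posts_per_user),
            "unique_categories_viewed_per_user": _stats(
                self.unique_categories_viewed_per_user
            ),
            "unique_categories_posted_per_user": _stats(
                self.unique_categories_posted_per_user
            ),
            "final_cumulative_views": int(self.cumulative_daily_views.iloc[-1])
            if len(self.cumulative_daily_views)
            else 0,
            "final_cumulative_posts": int(self.cumulative_daily_posts.iloc[-1])
            if len(self.cumulative_daily_posts)
            else 0,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def descriptive_summary(events: pd.DataFrame) -> DescriptiveSummary:
    """Counts, per-user distributions and daily cumulative series for an event log."""
    if events.empty:
        raise ValueError("cannot summarise an empty event log")
    views = events[events["event_type"] == VIEW]
    posts = events[events["event_type"] == POST]

    def _cumulative_daily(sub: pd.DataFrame) -> pd.Series:
        if sub.empty:
            return pd.Series(dtype=np.int64)
        days = sub["timestamp"].dt.floor("D")
        counts = days.value_counts().sort_index()
        full = pd.date_range(counts.index.min(), counts.index.max(), freq="D")
        return counts.reindex(full, fill_value=0).cumsum()

    return DescriptiveSummary(
        n_users=int(events["user_id"].nunique()),
        n_posts=int(len(posts)),
        n_views=int(len(views)),
        n_categories=int(events["category_id"].nunique()),
        views_per_user=views.groupby("user_id").size(),
        posts_per_user=posts.groupby("user_id").size(),
        unique_categories_viewed_per_user=views.groupby("user_id")["category_id"].nunique(),
        unique_categories_posted_per_user=posts.groupby("user_id")["category_id"].nunique(),
        cumulative_daily_views=_cumulative_daily(views),
        cumulative_daily_posts=_cumulative_daily(posts),
    )
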