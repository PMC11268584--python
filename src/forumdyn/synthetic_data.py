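"""Synthetic forum event-log generator.

Produces timestamped view/post logs with the statistical structure the
analysis stages assume, so the whole pipeline is testable without access to
restricted data:

* heavy-tailed per-user activity (lognormal view counts),
* archetype-structured category preferences — each of 8 archetypes mixes a
  shared profile over high-severity ("Sexual", COPINE >= 7) categories with
  an archetype-specific profile over low-severity categories; three
  archetypes are narrow (sparse preferences) and five broad,
* per-user activity rhythms: session start times follow an inhomogeneous
  Poisson process whose rate is modulated by
  ``1 + amplitude * cos(2*pi*t/period + phase)`` for users assigned a
  24/12/6-hour period,
* bursty within-session timing: events per session follow a shifted negative
  binomial, gaps within a session are lognormal minutes truncated strictly
  below 60, and
  consecutive sessions are separated by strictly more than 60 minutes — so
  the one-hour segmentation rule recovers the generated sessions exactly.

Ground-truth labels (archetype, rhythm period, session counts) are returned
alongside the log for recovery tests; the analysis pipeline never reads them.

All randomness flows from seeded ``numpy.random.Generator`` instances; equal
seeds give byte-identical logs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .content_clusters import UserCategoryMatrix
from .event_log import EVENT_COLUMNS, POST, VIEW, segment_for_grade

__all__ = [
    "Lognormal",
    "GeneratorConfig",
    "SyntheticUser",
    "GroundTruth",
    "default_config",
    "sexual_category_ids",
    "generate_categories",
    "generate_population",
    "generate_events",
    "sample_view_counts",
]

#: gap (minutes) that closes a session; generated sessions never straddle it
SESSION_GAP_MIN = 60.0
#: minimum spacing (minutes) enforced between consecutive generated sessions
INTER_SESSION_MIN = 61.0

_PERIOD_CHOICES = (24, 12, 6, 0)  # 0 encodes "no rhythm"


@dataclasses.dataclass(frozen=True)
class Lognormal:
    """Natural-log parameters of a lognormal law."""

    mu: float
    sigma: float

    @property
    def mean(self) -> float:
        return math.exp(self.mu + 0.5 * self.sigma**2)


@dataclasses.dataclass(frozen=True)
class NegBinomial:
    """Negative binomial by dispersion ``r`` and mean (``r=1`` is geometric).

    Sampled as a Gamma-Poisson mixture so non-integer ``r`` is allowed.
    """

    r: float
    mean: float

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.poisson(rng.gamma(self.r, self.mean / self.r)))


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic forum.  See :func:`default_config` for the
    calibrated defaults."""

    n_users: int = 500
    n_categories: int = 67
    n_archetypes: int = 8
    #: Dirichlet concentration per archetype for its low-severity profile
    #: (low = narrow preferences, high = broad)
    archetype_concentrations: tuple[float, ...] = ()
    #: fraction of categories with COPINE grade >= 7
    sexual_fraction: float = 0.5
    #: probability mass every archetype places on the shared Sexual profile
    core_overlap: float = 0.35
    #: Dirichlet concentration of the shared Sexual-category profile
    sexual_profile_concentration: float = 0.85
    #: total Dirichlet concentration of per-user weights around the archetype
    user_concentration: float = 60.0
    #: lognormal law of target views per user
    activity_law: Lognormal = Lognormal(mu=math.log(400.0), sigma=1.0)
    posts_per_user_mean: float = 10.0
    #: fraction of users who are producers (post at least once)
    producer_fraction: float = 0.2
    #: fractions of users with rhythm period 24 h / 12 h / 6 h / none
    period_mix: tuple[float, float, float, float] = (0.55, 0.20, 0.10, 0.15)
    #: relative modulation depth of the session-rate rhythm, in [0, 1)
    rhythm_amplitude: float = 0.9
    #: floor on the mean gap between a user's sessions (hours)
    session_gap_mean_hours: float = 6.0
    #: lognormal law of within-session inter-event gaps (minutes, < 60)
    within_session_gap_law: Lognormal = Lognormal(mu=0.0, sigma=1.0)
    #: law of the number of events beyond the first in a session
    events_per_session_law: NegBinomial = NegBinomial(r=2.5, mean=12.0)
    time_window: tuple[str, str] = ("2014-02-03T00:00:00Z", "2014-03-31T00:00:00Z")
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first invalid field."""
        if self.n_users < 1:
            raise ValueError("n_users must be positive")
        if self.n_categories < 2:
            raise ValueError("n_categories must be at least 2")
        if self.n_archetypes < 1:
            raise ValueError("n_archetypes must be positive")
        if len(self.archetype_concentrations) != self.n_archetypes:
            raise ValueError(
                "archetype_concentrations must have one entry per archetype"
            )
        if any(c <= 0 for c in self.archetype_concentrations):
            raise ValueError("archetype_concentrations must be strictly positive")
        if not 0.0 < self.sexual_fraction < 1.0:
            raise ValueError("sexual_fraction must be in (0, 1)")
        if not 0.0 <= self.core_overlap < 1.0:
            raise ValueError("core_overlap must be in [0, 1)")
        if self.sexual_profile_concentration <= 0:
            raise ValueError("sexual_profile_concentration must be strictly positive")
        if self.user_concentration <= 0:
            raise ValueError("user_concentration must be strictly positive")
        if self.activity_law.sigma <= 0:
            raise ValueError("activity_law.sigma must be strictly positive")
        if self.posts_per_user_mean < 1:
            raise ValueError("posts_per_user_mean must be at least 1")
        if not 0.0 < self.producer_fraction <= 1.0:
            raise ValueError("producer_fraction must be in (0, 1]")
        if len(self.period_mix) != 4 or any(f < 0 for f in self.period_mix):
            raise ValueError("period_mix must be 4 non-negative fractions")
        if abs(sum(self.period_mix) - 1.0) > 1e-9:
            raise ValueError("period_mix fractions must sum to 1")
        if not 0.0 <= self.rhythm_amplitude < 1.0:
            raise ValueError("rhythm_amplitude must be in [0, 1)")
        if self.session_gap_mean_hours <= 1.0:
            raise ValueError("session_gap_mean_hours must exceed 1 hour")
        if self.within_session_gap_law.mean >= SESSION_GAP_MIN:
            raise ValueError("within_session_gap_law mean must be below 60 minutes")
        if self.events_per_session_law.r <= 0 or self.events_per_session_law.mean <= 0:
            raise ValueError("events_per_session_law parameters must be strictly positive")
        start, end = self.window
        if not start < end:
            raise ValueError("time_window start must precede its end")

    @property
    def window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return (
            pd.Timestamp(self.time_window[0]),
            pd.Timestamp(self.time_window[1]),
        )


def default_config() -> GeneratorConfig:
    """Desk-scale default configuration (500 users, 8 weeks, 67 categories).

    The session-timing and preference parameters are calibrated so that, in
    expectation, segmented sessions have mean duration around 40 minutes with
    roughly 85% lasting at least 10 minutes and 25% at least 60 minutes,
    users view around 20 distinct categories on average, and producers post
    about 10 times each.  Three of the eight archetypes have narrow (sparse)
    preferences and five broad ones.
    """
    return GeneratorConfig(
        archetype_concentrations=(0.6, 0.6, 0.6, 2.0, 2.0, 2.0, 2.0, 2.0),
        activity_law=Lognormal(mu=math.log(330.0), sigma=1.0),
        within_session_gap_law=Lognormal(mu=0.579, sigma=1.2),
        events_per_session_law=NegBinomial(r=2.5, mean=12.0),
        time_window=("2014-02-03T00:00:00Z", "2014-03-31T00:00:00Z"),
    )


def sexual_category_ids(config: GeneratorConfig) -> np.ndarray:
    """Ids of the high-severity categories (the highest-numbered ones)."""
    n_sexual = int(round(config.sexual_fraction * config.n_categories))
    return np.arange(config.n_categories - n_sexual + 1, config.n_categories + 1)


def generate_categories(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Category table with COPINE grades consistent with the generator.

    High-severity categories get grades 7-10, the rest 1-6; the split matches
    :func:`sexual_category_ids` so the generated co-consumption structure
    lines up with the segment labels.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    sexual = set(sexual_category_ids(config).tolist())
    rows = []
    for cat in range(1, config.n_categories + 1):
        grade = int(rng.integers(7, 11) if cat in sexual else rng.integers(1, 7))
        rows.append(
            {
                "category_id": cat,
                "label": f"category_{cat:03d}",
                "copine_grade": grade,
                "segment": segment_for_grade(grade),
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class SyntheticUser:
    """Latent description of one synthetic user."""

    user_id: int
    archetype: int
    category_weights: np.ndarray
    rhythm_period_hours: int | None
    rhythm_phase: float
    target_views: int
    target_posts: int


@dataclasses.dataclass
class GroundTruth:
    """Generator-side labels for recovery tests (never read by the pipeline)."""

    archetypes: dict[int, int]
    rhythm_periods: dict[int, int | None]
    session_counts: dict[int, int]

    @property
    def n_sessions(self) -> int:
        return sum(self.session_counts.values())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "archetypes": {str(k): v for k, v in self.archetypes.items()},
            "rhythm_periods": {str(k): v for k, v in self.rhythm_periods.items()},
            "session_counts": {str(k): v for k, v in self.session_counts.items()},
            "n_sessions": self.n_sessions,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            archetypes={int(k): v for k, v in payload["archetypes"].items()},
            rhythm_periods={int(k): v for k, v in payload["rhythm_periods"].items()},
            session_counts={int(k): v for k, v in payload["session_counts"].items()},
        )


def _archetype_profiles(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Base category profiles, one row per archetype.

    Every archetype spends ``core_overlap`` of its mass on one shared profile
    over the Sexual categories (this plants the dense co-consumption core)
    and the rest on its own disjoint block of NonSexual categories (blocks
    are assigned round-robin), so archetypes are pairwise well separated.
    The archetype's Dirichlet concentration sets how evenly its mass spreads
    within the block: low = narrow preferences, high = broad.
    """
    n = config.n_categories
    sexual = sexual_category_ids(config) - 1  # 0-based
    nonsexual = np.setdiff1d(np.arange(n), sexual)
    shared_sexual = rng.dirichlet(
        np.full(len(sexual), config.sexual_profile_concentration)
    )
    profiles = np.zeros((config.n_archetypes, n))
    for a, conc in enumerate(config.archetype_concentrations):
        block = nonsexual[a :: config.n_archetypes]
        own = rng.dirichlet(np.full(len(block), conc))
        profiles[a, sexual] = config.core_overlap * shared_sexual
        profiles[a, block] = (1.0 - config.core_overlap) * own
    return profiles


def generate_population(config: GeneratorConfig, seed: int) -> list[SyntheticUser]:
    """Sample users: archetype, preference weights, rhythm, activity targets.

    Archetype membership is a uniform mixture over the archetypes; each
    user's category weights are a Dirichlet draw centred on the archetype
    profile with total concentration ``user_concentration``.  Deterministic
    given the seed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    profiles = _archetype_profiles(config, rng)
    users: list[SyntheticUser] = []
    for uid in range(1, config.n_users + 1):
        archetype = int(rng.integers(config.n_archetypes))
        alpha = np.maximum(config.user_concentration * profiles[archetype], 1e-8)
        weights = rng.dirichlet(alpha)
        period = int(rng.choice(_PERIOD_CHOICES, p=config.period_mix))
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
        target_views = max(1, int(round(rng.lognormal(
            config.activity_law.mu, config.activity_law.sigma
        ))))
        is_producer = rng.random() < config.producer_fraction
        target_posts = int(rng.geometric(1.0 / config.posts_per_user_mean)) if is_producer else 0
        users.append(
            SyntheticUser(
                user_id=uid,
                archetype=archetype,
                category_weights=weights,
                rhythm_period_hours=period if period else None,
                rhythm_phase=phase,
                target_views=target_views,
                target_posts=target_posts,
            )
        )
    return users


def _truncated_lognormal(
    rng: np.random.Generator, law: Lognormal, size: int, upper: float
) -> np.ndarray:
    """Lognormal draws conditioned to lie strictly below ``upper``."""
    out = rng.lognormal(law.mu, law.sigma, size)
    bad = out >= upper
    while bad.any():
        out[bad] = rng.lognormal(law.mu, law.sigma, int(bad.sum()))
        bad = out >= upper
    return out


def _user_event_times(
    user: SyntheticUser, config: GeneratorConfig, rng: np.random.Generator, window_hours: float
) -> tuple[np.ndarray, int]:
    """Event times (hours from window start) for one user, plus session count.

    Session starts follow a thinned Poisson process (cosine-modulated when
    the user has a rhythm) with a dead time that keeps consecutive sessions
    strictly more than 60 minutes apart.
    """
    law = config.events_per_session_law
    mean_events = 1.0 + law.mean
    n_sessions_target = math.ceil(user.target_views / mean_events)
    rate = min(n_sessions_target / window_hours, 1.0 / config.session_gap_mean_hours)
    amp = config.rhythm_amplitude if user.rhythm_period_hours else 0.0
    rate_cand = rate * (1.0 + amp)

    n_cand = rng.poisson(rate_cand * window_hours)
    candidates = np.sort(rng.uniform(0.0, window_hours, n_cand))
    if amp > 0.0:
        density = 1.0 + amp * np.cos(
            2.0 * math.pi * candidates / user.rhythm_period_hours + user.rhythm_phase
        )
        keep = rng.random(n_cand) < density / (1.0 + amp)
        candidates = candidates[keep]

    times: list[np.ndarray] = []
    remaining = user.target_views
    free_from = -math.inf
    n_sessions = 0
    for start in candidates:
        if remaining <= 0:
            break
        if start < free_from:
            continue
        n_events = min(1 + law.sample(rng), remaining)
        # truncate one second short of the threshold so that flooring
        # timestamps to whole seconds can never produce a 60-minute gap
        gaps_min = _truncated_lognormal(
            rng, config.within_session_gap_law, n_events - 1, SESSION_GAP_MIN - 1.0 / 60.0
        )
        offsets_h = np.concatenate(([0.0], np.cumsum(gaps_min) / 60.0))
        session_times = start + offsets_h
        session_times = session_times[session_times < window_hours]
        if len(session_times) == 0:
            continue
        times.append(session_times)
        remaining -= len(session_times)
        free_from = session_times[-1] + INTER_SESSION_MIN / 60.0
        n_sessions += 1
    if not times:
        # guarantee at least one event inside the window
        t0 = float(rng.uniform(0.0, window_hours))
        times.append(np.array([t0]))
        n_sessions = 1
    return np.concatenate(times), n_sessions


def generate_events(
    population: Sequence[SyntheticUser], config: GeneratorConfig, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the event log for a population.

    Returns the log (sorted by user then time, second resolution, all
    timestamps inside the configured window) together with the ground truth.
    Post events are assigned to producers by converting ``target_posts`` of
    their events; every event's category is drawn from the user's weights.
    """
    config.validate()
    if not population:
        raise ValueError("population must not be empty")
    rng = np.random.default_rng(seed)
    start_ts, end_ts = config.window
    window_hours = (end_ts - start_ts).total_seconds() / 3600.0

    frames = []
    truth_sessions: dict[int, int] = {}
    post_counter = 10_000_000
    cat_ids = np.arange(1, config.n_categories + 1)
    for user in population:
        times_h, n_sessions = _user_event_times(user, config, rng, window_hours)
        n = len(times_h)
        truth_sessions[user.user_id] = n_sessions
        categories = rng.choice(cat_ids, size=n, p=user.category_weights)
        event_type = np.full(n, VIEW, dtype=object)
        n_posts = min(user.target_posts, n)
        if n_posts > 0:
            post_idx = rng.choice(n, size=n_posts, replace=False)
            event_type[post_idx] = POST
        post_ids = categories * 1000 + rng.integers(0, 140, size=n)
        is_post = event_type == POST
        post_ids[is_post] = post_counter + np.arange(int(is_post.sum()))
        post_counter += int(is_post.sum())
        timestamps = start_ts + pd.to_timedelta(
            np.floor(times_h * 3600.0).astype(np.int64), unit="s"
        )
        frames.append(
            pd.DataFrame(
                {
                    "user_id": user.user_id,
                    "post_id": post_ids,
                    "category_id": categories,
                    "event_type": event_type,
                    "timestamp": timestamps,
                }
            )
        )
    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values(["user_id", "timestamp"], kind="stable", ignore_index=True)
    events.insert(0, "event_id", np.arange(1, len(events) + 1, dtype=np.int64))
    events = events[EVENT_COLUMNS]

    truth = GroundTruth(
        archetypes={u.user_id: u.archetype for u in population},
        rhythm_periods={u.user_id: u.rhythm_period_hours for u in population},
        session_counts=truth_sessions,
    )
    return events, truth


def sample_view_counts(
    population: Sequence[SyntheticUser], config: GeneratorConfig, seed: int
) -> UserCategoryMatrix:
    """Draw each user's category view counts directly (no event timing).

    Marginally equivalent to counting the view events of a generated log:
    categories are i.i.d. draws from the user's weights, so counts are
    multinomial with the user's view target.  Useful for preference-recovery
    tests where timing is irrelevant.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    counts = np.stack(
        [rng.multinomial(u.target_views, u.category_weights) for u in population]
    ).astype(np.int64)
    shares = counts / counts.sum(axis=1, keepdims=True)
    return UserCategoryMatrix(
        user_ids=np.array([u.user_id for u in population]),
        category_ids=np.arange(1, config.n_categories + 1),
        counts=counts,
        shares=shares,
    )
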