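"""User-category preference matrices, k-means clustering, elbow selection,
and Shannon-entropy breadth profiling.

Users are represented by their view *shares* across categories (row-normalised
view counts), so clustering reflects where a user's attention goes rather than
how active they are.  The number of clusters is chosen with the elbow rule:
the k maximising the (centered) second difference of the k-means inertia
curve, i.e. the point where the marginal variance gain collapses.  Preference
breadth is the Shannon entropy of a user's share vector, in bits.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .event_log import VIEW

__all__ = [
    "DEFAULT_MIN_VIEWS",
    "DEFAULT_K_RANGE",
    "DEFAULT_RESTARTS",
    "UserCategoryMatrix",
    "ClusteringResult",
    "ElbowSelection",
    "EntropySummary",
    "build_view_share_matrix",
    "kmeans_inertia_curve",
    "select_k_elbow",
    "cluster_users",
    "shannon_entropy",
    "cluster_entropy_summary",
]

DEFAULT_MIN_VIEWS = 100
DEFAULT_K_RANGE = range(2, 16)
DEFAULT_RESTARTS = 10


@dataclasses.dataclass
class UserCategoryMatrix:
    """Per-user category view counts and row-normalised shares."""

    user_ids: np.ndarray
    category_ids: np.ndarray
    counts: np.ndarray
    shares: np.ndarray

    @property
    def n_users(self) -> int:
        return len(self.user_ids)

    @property
    def n_categories(self) -> int:
        return len(self.category_ids)


@dataclasses.dataclass
class ClusteringResult:
    """K-means assignment of users to preference clusters."""

    k: int
    assignments: np.ndarray
    inertia: float
    seed: int


@dataclasses.dataclass
class ElbowSelection:
    """Cluster count chosen by the maximum-second-difference elbow rule.

    ``degenerate`` flags a flat or linear inertia curve, for which no elbow
    exists and the smallest candidate k is returned.
    """

    k: int
    second_differences: dict[int, float]
    degenerate: bool


def build_view_share_matrix(
    events: pd.DataFrame, min_views: int = DEFAULT_MIN_VIEWS
) -> UserCategoryMatrix:
    """Build the user x category view-count matrix and its row shares.

    Only view events are counted; users with fewer than ``min_views`` total
    views are dropped (the less-active-user filter).  Raises ``ValueError``
    if no view events exist or no user survives the filter.
    """
    views = events[events["event_type"] == VIEW]
    if views.empty:
        raise ValueError("no view events to build a matrix from")
    counts = pd.crosstab(views["user_id"], views["category_id"])
    counts = counts[counts.sum(axis=1) >= min_views]
    if counts.empty:
        raise ValueError(f"no user has at least {min_views} views")
    arr = counts.to_numpy(dtype=float)
    shares = arr / arr.sum(axis=1, keepdims=True)
    return UserCategoryMatrix(
        user_ids=counts.index.to_numpy(),
        category_ids=counts.columns.to_numpy(),
        counts=arr.astype(np.int64),
        shares=shares,
    )


def kmeans_inertia_curve(
    matrix: UserCategoryMatrix,
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
) -> dict[int, float]:
    """Best within-cluster sum of squares over restarts, for each k.

    Runs k-means on the shares matrix with ``restarts`` random
    initialisations per k; deterministic given ``seed``.
    """
    ks = sorted(set(int(k) for k in k_range))
    if max(ks) > matrix.n_users:
        raise ValueError(
            f"k={max(ks)} exceeds the number of retained users ({matrix.n_users})"
        )
    curve: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        km.fit(matrix.shares)
        curve[k] = float(km.inertia_)
    return curve


def select_k_elbow(inertia_curve: Mapping[int, float]) -> ElbowSelection:
    """Pick k at the elbow of an inertia curve.

    The elbow is the k with maximal centered second difference
    ``I(k-1) - 2 I(k) + I(k+1)`` over consecutive k values; ties are broken
    toward smaller k.  A flat or linear curve has no curvature anywhere; the
    smallest candidate k is returned with ``degenerate=True``.
    """
    ks = sorted(inertia_curve)
    if len(ks) < 4:
        raise ValueError("need an inertia curve over at least 4 consecutive k values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("inertia curve must cover consecutive k values")
    inertia = np.array([float(inertia_curve[k]) for k in ks])
    d2 = {ks[i]: inertia[i - 1] - 2 * inertia[i] + inertia[i + 1] for i in range(1, len(ks) - 1)}
    scale = max(inertia.max() - inertia.min(), 1.0)
    best_k = min(d2, key=lambda k: (-d2[k], k))
    if d2[best_k] <= 1e-9 * scale:
        return ElbowSelection(k=ks[0], second_differences=d2, degenerate=True)
    return ElbowSelection(k=int(best_k), second_differences=d2, degenerate=False)


def cluster_users(
    matrix: UserCategoryMatrix,
    k: int,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
) -> ClusteringResult:
    """K-means assignments on the shares matrix (best of ``restarts`` runs)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > matrix.n_users:
        raise ValueError(f"k={k} exceeds the number of retained users")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(matrix.shares)
    return ClusteringResult(k=int(k), assignments=labels, inertia=float(km.inertia_), seed=int(seed))


def shannon_entropy(shares: np.ndarray | Sequence[float]) -> float:
    """Shannon entropy, in bits, of a probability vector (0 log 0 := 0)."""
    p = np.asarray(shares, dtype=float)
    if (p < 0).any():
        raise ValueError("shares must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"shares must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclasses.dataclass
class EntropySummary:
    """Per-user preference entropies and their distribution within clusters."""

    per_user_entropy: pd.Series
    per_cluster: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            str(int(row.cluster)): {
                "n": int(row["n"]),
                "mean": float(row["mean"]),
                "q25": float(row["q25"]),
                "median": float(row["median"]),
                "q75": float(row["q75"]),
            }
            for _, row in self.per_cluster.iterrows()
        }


def cluster_entropy_summary(
    result: ClusteringResult, matrix: UserCategoryMatrix
) -> EntropySummary:
    """Group per-user share entropies by cluster and summarise each group."""
    if len(result.assignments) != matrix.n_users:
        raise ValueError("clustering result does not match the matrix")
    entropies = pd.Series(
        [shannon_entropy(row) for row in matrix.shares],
        index=pd.Index(matrix.user_ids, name="user_id"),
        name="entropy_bits",
    )
    df = pd.DataFrame({"entropy": entropies.to_numpy(), "cluster": result.assignments})
    per_cluster = (
        df.groupby("cluster")["entropy"]
        .agg(
            n="size",
            mean="mean",
            q25=lambda s: s.quantile(0.25),
            median="median",
            q75=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    return EntropySummary(per_user_entropy=entropies, per_cluster=per_cluster)
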