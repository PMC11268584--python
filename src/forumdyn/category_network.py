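"""Category co-consumption network weighted by relative risk, with
COPINE-segment core-periphery analysis.

Two categories are linked when at least one user viewed content in both.
Edge strength is the relative risk (lift)

    RR_ij = C_ij * N / (P_i * P_j)

where ``C_ij`` counts users who viewed both categories, ``N`` is the number
of distinct viewing users, and the prevalence ``P_i`` is the number of
distinct users with at least one view in category ``i`` (a count, not a
proportion).  RR = 1 means the two audiences overlap exactly as expected
under independence; the network core is obtained by dropping edges with
RR < 1 (the boundary RR = 1 is kept) and removing the nodes this isolates.
Centrality of the filtered graph is read off its k-core decomposition.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .event_log import VIEW

__all__ = [
    "ConsumptionTable",
    "CategoryNetwork",
    "CoreComposition",
    "consumption_table",
    "relative_risk",
    "build_rr_network",
    "filter_core",
    "core_composition",
    "edges_frame",
    "write_graphml",
]


@dataclasses.dataclass
class ConsumptionTable:
    """Distinct-consumer sets per category and the total user count N."""

    n_users: int
    consumers: dict[int, frozenset[int]]

    @property
    def prevalence(self) -> dict[int, int]:
        """P_i: number of distinct users with at least one view in category i."""
        return {c: len(users) for c, users in self.consumers.items()}


@dataclasses.dataclass
class CategoryNetwork:
    """Categories as nodes, co-consumption edges weighted by relative risk."""

    graph: nx.Graph
    filtered: bool = False


@dataclasses.dataclass
class CoreComposition:
    """COPINE-segment makeup of the maximum k-core of a filtered network."""

    max_k: int
    fractions: dict[str, float]
    coreness: dict[int, int]


def consumption_table(events: pd.DataFrame) -> ConsumptionTable:
    """Build per-category consumer sets from view events.

    Repeated views by the same user count once (set semantics); N is the
    number of distinct users with at least one view anywhere.
    """
    views = events[events["event_type"] == VIEW]
    if views.empty:
        raise ValueError("no view events to build a consumption table from")
    consumers = {
        int(cat): frozenset(int(u) for u in group["user_id"].unique())
        for cat, group in views.groupby("category_id")
    }
    return ConsumptionTable(n_users=int(views["user_id"].nunique()), consumers=consumers)


def relative_risk(c_ij: int, n: int, p_i: int, p_j: int) -> float:
    """Relative risk ``C_ij * N / (P_i * P_j)`` of co-consumption.

    Requires positive N and prevalences and ``0 <= C_ij <= min(P_i, P_j)``.
    """
    if n <= 0:
        raise ValueError("N must be positive")
    if p_i <= 0 or p_j <= 0:
        raise ValueError("prevalences must be positive")
    if not 0 <= c_ij <= min(p_i, p_j):
        raise ValueError("C_ij must be between 0 and min(P_i, P_j)")
    return float(c_ij) * float(n) / (float(p_i) * float(p_j))


def build_rr_network(
    table: ConsumptionTable, categories: pd.DataFrame
) -> CategoryNetwork:
    """Assemble the unfiltered co-consumption graph.

    One node per consumed category (tagged with label, COPINE grade and
    segment from the category table); one edge per unordered pair with at
    least one shared consumer, carrying ``c_ij`` and ``rr`` attributes.
    Raises ``ValueError`` if a consumed category is missing from the table.
    """
    meta = categories.set_index("category_id")
    missing = sorted(set(table.consumers) - set(meta.index))
    if missing:
        raise ValueError(f"categories present in events but not in the table: {missing}")
    g = nx.Graph()
    for cat in sorted(table.consumers):
        g.add_node(
            cat,
            label=str(meta.loc[cat, "label"]),
            copine_grade=int(meta.loc[cat, "copine_grade"]),
            segment=str(meta.loc[cat, "segment"]),
        )
    prevalence = table.prevalence
    for i, j in combinations(sorted(table.consumers), 2):
        c_ij = len(table.consumers[i] & table.consumers[j])
        if c_ij >= 1:
            rr = relative_risk(c_ij, table.n_users, prevalence[i], prevalence[j])
            g.add_edge(i, j, c_ij=c_ij, rr=rr)
    return CategoryNetwork(graph=g, filtered=False)


def filter_core(network: CategoryNetwork, rr_min: float = 1.0) -> CategoryNetwork:
    """Drop edges with RR below ``rr_min`` and remove the nodes left isolated.

    The boundary ``rr == rr_min`` is retained.  Idempotent.
    """
    g = network.graph.copy()
    weak = [(u, v) for u, v, rr in g.edges(data="rr") if rr < rr_min]
    g.remove_edges_from(weak)
    g.remove_nodes_from(list(nx.isolates(g)))
    return CategoryNetwork(graph=g, filtered=True)


def core_composition(network: CategoryNetwork) -> CoreComposition:
    """COPINE-segment fractions in the maximum k-core of a filtered network."""
    if not network.filtered:
        raise ValueError("core composition is defined on the filtered network")
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot analyse an empty network")
    coreness = nx.core_number(g)
    max_k = max(coreness.values())
    core_nodes = [n for n, k in coreness.items() if k == max_k]
    segments = [g.nodes[n]["segment"] for n in core_nodes]
    fractions = {
        seg: segments.count(seg) / len(core_nodes) for seg in sorted(set(segments))
    }
    return CoreComposition(max_k=int(max_k), fractions=fractions, coreness=coreness)


def edges_frame(network: CategoryNetwork) -> pd.DataFrame:
    """Edge list as a DataFrame (category_i < category_j)."""
    rows = [
        {"category_i": min(u, v), "category_j": max(u, v), "c_ij": d["c_ij"], "rr": d["rr"]}
        for u, v, d in network.graph.edges(data=True)
    ]
    return (
        pd.DataFrame(rows, columns=["category_i", "category_j", "c_ij", "rr"])
        .sort_values(["category_i", "category_j"], ignore_index=True)
    )


def write_graphml(network: CategoryNetwork, path: str | Path) -> None:
    """Export the network to GraphML, annotating nodes with their coreness."""
    g = network.graph.copy()
    if g.number_of_nodes():
        for node, k in nx.core_number(g).items():
            g.nodes[node]["coreness"] = int(k)
    nx.write_graphml(g, path)
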