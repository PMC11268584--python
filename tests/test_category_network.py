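import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from forumdyn import category_network as net
from forumdyn import event_log as ev
from forumdyn import synthetic_data as syn
from forumdyn.event_log import POST, VIEW

from conftest import make_events


def categories_frame(grades):
    return pd.DataFrame(
        {
            "category_id": sorted(grades),
            "label": [f"c{c}" for c in sorted(grades)],
            "copine_grade": [grades[c] for c in sorted(grades)],
            "segment": [ev.segment_for_grade(grades[c]) for c in sorted(grades)],
        }
    )


class TestConsumptionTable:
    def test_direct_counts(self):
        events = make_events(
            [(1, 0, VIEW, 1), (1, 1, VIEW, 2), (2, 0, VIEW, 1), (3, 0, VIEW, 2)]
        )
        table = net.consumption_table(events)
        assert table.n_users == 3
        assert table.prevalence == {1: 2, 2: 2}

    def test_repeated_views_count_once(self):
        events = make_events([(1, i, VIEW, 1) for i in range(10)])
        table = net.consumption_table(events)
        assert table.prevalence == {1: 1}

    def test_posts_do_not_create_consumption(self):
        events = make_events([(1, 0, VIEW, 1), (2, 0, POST, 2)])
        table = net.consumption_table(events)
        assert 2 not in table.consumers
        assert table.n_users == 1

    def test_no_views_rejected(self):
        with pytest.raises(ValueError):
            net.consumption_table(make_events([(1, 0, POST, 1)]))


class TestRelativeRisk:
    def test_independence_counts_give_one(self):
        assert net.relative_risk(25, 100, 50, 50) == pytest.approx(1.0)

    def test_excess_overlap(self):
        assert net.relative_risk(40, 100, 50, 50) == pytest.approx(1.6)

    def test_disjoint_audiences_give_zero(self):
        assert net.relative_risk(0, 100, 50, 50) == 0.0

    @pytest.mark.parametrize(
        "args", [(1, 0, 5, 5), (1, 10, 0, 5), (6, 10, 5, 5), (-1, 10, 5, 5)]
    )
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            net.relative_risk(*args)


class TestBuildNetwork:
    def test_toy_network_edge_values(self):
        # u1 views {a=1, b=2}, u2 views {a}, u3 views {b}
        events = make_events(
            [(1, 0, VIEW, 1), (1, 1, VIEW, 2), (2, 0, VIEW, 1), (3, 0, VIEW, 2)]
        )
        network = net.build_rr_network(
            net.consumption_table(events), categories_frame({1: 3, 2: 8})
        )
        assert network.graph.number_of_edges() == 1
        d = network.graph.edges[1, 2]
        assert d["c_ij"] == 1
        assert d["rr"] == pytest.approx(1 * 3 / (2 * 2))
        assert network.graph.nodes[1]["segment"] == ev.NON_SEXUAL
        assert network.graph.nodes[2]["segment"] == ev.SEXUAL

    def test_pair_without_shared_consumer_has_no_edge(self):
        events = make_events([(1, 0, VIEW, 1), (2, 0, VIEW, 2)])
        network = net.build_rr_network(
            net.consumption_table(events), categories_frame({1: 1, 2: 1})
        )
        assert network.graph.number_of_edges() == 0

    def test_missing_category_rejected(self):
        events = make_events([(1, 0, VIEW, 9)])
        with pytest.raises(ValueError, match="9"):
            net.build_rr_network(net.consumption_table(events), categories_frame({1: 1}))

    @given(
        data=st.lists(
            st.tuples(st.integers(1, 8), st.integers(1, 5)), min_size=1, max_size=40
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rr_matches_brute_force_on_random_toy_logs(self, data):
        """Every edge RR equals the brute-force computation from per-user
        category sets, for random logs of <= 8 users x <= 5 categories."""
        events = make_events(
            [(u, i, VIEW, c) for i, (u, c) in enumerate(data)]
        )
        table = net.consumption_table(events)
        network = net.build_rr_network(
            table, categories_frame({c: 1 for c in range(1, 6)})
        )
        # brute force from scratch
        sets = {}
        for u, c in data:
            sets.setdefault(u, set()).add(c)
        n = len(sets)
        cats = sorted({c for _, c in data})
        for i, j in itertools.combinations(cats, 2):
            shared = sum(1 for s in sets.values() if i in s and j in s)
            p_i = sum(1 for s in sets.values() if i in s)
            p_j = sum(1 for s in sets.values() if j in s)
            if shared >= 1:
                assert network.graph.edges[i, j]["rr"] == pytest.approx(
                    shared * n / (p_i * p_j)
                )
            else:
                assert not network.graph.has_edge(i, j)


class TestFilterCore:
    def _network(self, edges, grades):
        g = nx.Graph()
        for c in grades:
            g.add_node(c, label=f"c{c}", copine_grade=grades[c],
                       segment=ev.segment_for_grade(grades[c]))
        for u, v, rr in edges:
            g.add_edge(u, v, c_ij=1, rr=rr)
        return net.CategoryNetwork(graph=g, filtered=False)

    def test_boundary_rr_kept_weak_dropped(self):
        network = self._network(
            [(1, 2, 0.5), (2, 3, 1.0), (3, 4, 1.6)], {1: 1, 2: 1, 3: 1, 4: 1}
        )
        filtered = net.filter_core(network)
        rrs = sorted(d["rr"] for _, _, d in filtered.graph.edges(data=True))
        assert rrs == [1.0, 1.6]

    def test_isolated_nodes_removed(self):
        network = self._network([(1, 2, 0.5), (2, 3, 1.5)], {1: 1, 2: 1, 3: 1})
        filtered = net.filter_core(network)
        assert set(filtered.graph.nodes) == {2, 3}

    def test_empty_edge_set_gives_empty_network(self):
        network = self._network([], {1: 1})
        filtered = net.filter_core(network)
        assert filtered.graph.number_of_nodes() == 0

    def test_idempotent_and_never_grows(self):
        network = self._network(
            [(1, 2, 0.9), (2, 3, 1.2), (3, 4, 2.0), (4, 5, 0.2)],
            {i: 1 for i in range(1, 6)},
        )
        once = net.filter_core(network)
        twice = net.filter_core(once)
        assert set(once.graph.nodes) == set(twice.graph.nodes)
        assert set(once.graph.edges) == set(twice.graph.edges)
        assert once.graph.number_of_nodes() <= network.graph.number_of_nodes()


class TestCoreComposition:
    def test_clique_core_with_pendants(self):
        g = nx.Graph()
        for c in (1, 2, 3, 4):
            g.add_node(c, segment=ev.SEXUAL)
        for c in (5, 6, 7):
            g.add_node(c, segment=ev.NON_SEXUAL)
        for u, v in itertools.combinations((1, 2, 3, 4), 2):
            g.add_edge(u, v, rr=2.0)
        g.add_edge(1, 5, rr=1.5)
        g.add_edge(2, 6, rr=1.5)
        g.add_edge(3, 7, rr=1.5)
        comp = net.core_composition(net.CategoryNetwork(graph=g, filtered=True))
        assert comp.max_k == 3
        assert comp.fractions == {ev.SEXUAL: 1.0}

    def test_star_graph_is_single_core(self):
        g = nx.star_graph(5)
        nx.set_node_attributes(g, ev.NON_SEXUAL, "segment")
        comp = net.core_composition(net.CategoryNetwork(graph=g, filtered=True))
        assert comp.max_k == 1
        assert comp.fractions == {ev.NON_SEXUAL: 1.0}
        assert set(comp.coreness.values()) == {1}

    def test_unfiltered_network_rejected(self):
        g = nx.Graph()
        with pytest.raises(ValueError):
            net.core_composition(net.CategoryNetwork(graph=g, filtered=False))

    def test_synthetic_core_is_predominantly_sexual(self, default_log):
        """The generator plants shared consumption on high-severity categories,
        so they dominate the maximum k-core of the filtered RR network."""
        cfg, _, events, _ = default_log
        categories = syn.generate_categories(cfg, seed=77)
        table = net.consumption_table(events)
        filtered = net.filter_core(net.build_rr_network(table, categories))
        comp = net.core_composition(filtered)
        sexual = comp.fractions.get(ev.SEXUAL, 0.0)
        nonsexual = comp.fractions.get(ev.NON_SEXUAL, 0.0)
        assert sexual >= nonsexual


class TestIndependenceSimulation:
    def test_rr_tends_to_one_under_independence(self):
        """With independent per-user consumption at fixed prevalences, the
        empirical RR converges to 1 within Monte-Carlo error."""
        rng = np.random.default_rng(5)
        n = 20_000
        a = rng.random(n) < 0.3
        b = rng.random(n) < 0.4
        rr = net.relative_risk(int((a & b).sum()), n, int(a.sum()), int(b.sum()))
        assert rr == pytest.approx(1.0, abs=0.05)


class TestExports:
    def test_edges_frame_sorted_pairs(self):
        events = make_events(
            [(1, 0, VIEW, 2), (1, 1, VIEW, 1), (2, 0, VIEW, 1), (2, 1, VIEW, 2)]
        )
        network = net.build_rr_network(
            net.consumption_table(events), categories_frame({1: 1, 2: 1})
        )
        frame = net.edges_frame(network)
        assert frame.columns.tolist() == ["category_i", "category_j", "c_ij", "rr"]
        assert (frame["category_i"] < frame["category_j"]).all()

    def test_graphml_round_trip_keeps_attributes(self, tmp_path):
        events = make_events(
            [(1, 0, VIEW, 1), (1, 1, VIEW, 2), (2, 0, VIEW, 1), (2, 1, VIEW, 2)]
        )
        network = net.build_rr_network(
            net.consumption_table(events), categories_frame({1: 3, 2: 9})
        )
        path = tmp_path / "net.graphml"
        net.write_graphml(network, path)
        back = nx.read_graphml(path)
        node = back.nodes["1"]
        assert node["segment"] == ev.NON_SEXUAL
        assert node["copine_grade"] == 3
        assert "coreness" in node
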