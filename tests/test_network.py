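"""Bipartite network construction, topology statistics and centrality."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from natprodnet.network import (
    BipartiteNetwork,
    InteractionEdge,
    admissible_edges,
    betweenness,
    build_network,
    centrality_table,
    components,
    degree,
    degree_sequence,
    density,
    fit_power_law,
    hit_rate,
    mean_shortest_path,
    network_stats,
    rank_hubs_bottlenecks,
)
from natprodnet.synthetic_data import GeneratorConfig, gen_interaction_network

from conftest import brute_force_betweenness, random_small_graph


def edges_df(pairs):
    return pd.DataFrame(pairs, columns=["compound_id", "target_id", "score"])


def star(n_leaves=5):
    return build_network(edges_df([("c0", f"t{i}", 1.0) for i in range(n_leaves)]))


def from_graph(g: nx.Graph) -> BipartiteNetwork:
    return BipartiteNetwork(graph=g)


# ---------------------------------------------------------------------------
# construction and admissibility
# ---------------------------------------------------------------------------

class TestBuildNetwork:
    def test_no_threshold_keeps_all_edges(self):
        net = build_network(edges_df([("c1", "t1", 5), ("c1", "t2", 6), ("c2", "t1", 7)]))
        assert net.n_edges == 3

    def test_score_at_or_below_threshold_excluded(self):
        refs = {"t1": 5.0}
        net = build_network(edges_df([("c1", "t1", 8.5)]), threshold=9.0, reference_scores=refs)
        assert net.n_edges == 0

    def test_score_below_reference_ligand_excluded(self):
        refs = {"t1": 9.8}
        net = build_network(edges_df([("c1", "t1", 9.5)]), threshold=9.0, reference_scores=refs)
        assert net.n_edges == 0

    def test_missing_reference_error_names_target(self):
        with pytest.raises(ValueError, match="t_missing"):
            build_network(edges_df([("c1", "t_missing", 9.5)]), threshold=9.0, reference_scores={"t1": 1.0})

    def test_duplicate_pairs_aggregated_by_max_score(self):
        adm = admissible_edges(edges_df([("c1", "t1", 5.0), ("c1", "t1", 9.5)]),
                               threshold=9.0, reference_scores={"t1": 8.0})
        assert len(adm) == 1 and adm.loc[0, "score"] == 9.5

    def test_interaction_edge_objects_accepted(self):
        net = build_network([InteractionEdge("c1", "t1", 5.0), InteractionEdge("c2", "t1", 6.0)])
        assert net.compounds == {"c1", "c2"} and net.targets == {"t1"}

    def test_raising_threshold_is_monotone(self):
        rng = np.random.default_rng(7)
        table = edges_df([(f"c{i % 20}", f"t{i % 7}", float(rng.uniform(0, 12)))
                          for i in range(150)])
        refs = {f"t{i}": float(rng.uniform(3, 9)) for i in range(7)}
        prev = None
        for thr in (2.0, 4.0, 6.0, 8.0, 10.0):
            adm = admissible_edges(table, thr, refs)
            pairs = set(zip(adm["compound_id"], adm["target_id"]))
            if prev is not None:
                assert pairs <= prev
            prev = pairs


class TestHitRate:
    def test_every_compound_hits(self):
        table = edges_df([("c1", "t1", 10.0), ("c2", "t1", 11.0)])
        assert hit_rate(table, 9.0, {"t1": 9.5}) == 1.0

    def test_no_passing_edges(self):
        table = edges_df([("c1", "t1", 5.0), ("c2", "t1", 6.0)])
        assert hit_rate(table, 9.0, {"t1": 9.5}) == 0.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(8)
        rows = [(f"c{i}", f"t{j}", float(rng.uniform(0, 12)))
                for i in range(40) for j in rng.choice(10, size=4, replace=False)]
        refs = {f"t{j}": float(rng.uniform(4, 10)) for j in range(10)}
        table = edges_df(rows)
        expected = len({c for c, t, s in rows if s > 7.0 and s > refs[t]}) / 40
        assert hit_rate(table, 7.0, refs) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# centrality
# ---------------------------------------------------------------------------

class TestDegree:
    def test_star_center_degree(self):
        deg = degree(star(5))
        assert deg["c0"] == 5 and all(deg[f"t{i}"] == 1 for i in range(5))

    def test_matches_adjacency_row_sums(self):
        rng = np.random.default_rng(9)
        nodes, edges = random_small_graph(rng)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        adj = nx.to_numpy_array(g, nodelist=nodes)
        deg = degree(from_graph(g))
        for i, n in enumerate(nodes):
            assert deg[n] == adj[i].sum()

    def test_handshake_identity_on_synthetic_network(self):
        edges, _ = gen_interaction_network(GeneratorConfig(seed=3, n_compounds=100, n_targets=30))
        net = build_network(edges)
        stats = network_stats(net)
        assert stats.mean_targets_per_compound * stats.n_compounds == pytest.approx(stats.n_edges)
        assert stats.mean_hits_per_target * stats.n_targets == pytest.approx(stats.n_edges)
        assert sum(degree_sequence(net, "compound")) == sum(degree_sequence(net, "target")) == stats.n_edges


class TestBetweenness:
    def test_path_middle_node(self):
        net = build_network(edges_df([("a", "b", 1), ("c", "b", 1)]))
        btw = betweenness(net)
        assert btw["b"] == pytest.approx(1.0)
        assert btw["a"] == btw["c"] == 0.0

    def test_star_center_is_one(self):
        btw = betweenness(star(5))  # N = 6
        assert btw["c0"] == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            nodes, edges = random_small_graph(rng)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            got = betweenness(from_graph(g))
            expected = brute_force_betweenness(nodes, edges)
            for n in nodes:
                assert got[n] == pytest.approx(expected[n], abs=1e-9), n


class TestRanking:
    def _table(self):
        return pd.DataFrame({
            "node_id": ["a", "b", "c"],
            "partition": ["compound"] * 3,
            "degree": [5, 3, 1],
            "betweenness": [0.1, 0.5, 0.2],
        })

    def test_hub_order_by_degree(self):
        hubs, _ = rank_hubs_bottlenecks(self._table(), top_k=3)
        assert list(hubs["node_id"]) == ["a", "b", "c"]

    def test_bottleneck_order_by_betweenness(self):
        _, bn = rank_hubs_bottlenecks(self._table(), top_k=3)
        assert list(bn["node_id"]) == ["b", "c", "a"]

    def test_degree_tie_broken_by_betweenness_then_id(self):
        t = pd.DataFrame({
            "node_id": ["x", "y", "z"],
            "partition": ["compound"] * 3,
            "degree": [4, 4, 4],
            "betweenness": [0.2, 0.3, 0.2],
        })
        hubs, _ = rank_hubs_bottlenecks(t, top_k=3)
        assert list(hubs["node_id"]) == ["y", "x", "z"]


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

class TestComponents:
    def test_connected_graph_single_component(self):
        comps, giant = components(star(4))
        assert len(comps) == 1 and giant == 1.0

    def test_equal_components_ordered_by_smallest_node_id(self):
        net = build_network(edges_df([("a1", "z1", 1), ("b1", "y1", 1)]))
        comps, giant = components(net)
        assert giant == 0.5
        assert min(comps[0]) < min(comps[1])

    def test_giant_fraction_on_fragmented_network(self):
        net = build_network(edges_df([("a", "t1", 1), ("b", "t1", 1), ("c", "t2", 1)]))
        comps, giant = components(net)
        assert [len(c) for c in comps] == [3, 2]
        assert giant == pytest.approx(3 / 5)


class TestMeanShortestPath:
    def test_three_node_path(self):
        net = build_network(edges_df([("a", "b", 1), ("c", "b", 1)]))
        assert mean_shortest_path(net) == pytest.approx(4 / 3)

    def test_complete_bipartite_k22(self):
        net = build_network(edges_df([(c, t, 1) for c in ("c1", "c2") for t in ("t1", "t2")]))
        assert mean_shortest_path(net) == pytest.approx(4 / 3)

    def test_star_k14(self):
        assert mean_shortest_path(star(4)) == pytest.approx(1.6)

    def test_disconnected_pairs_excluded(self):
        net = build_network(edges_df([("a", "t1", 1), ("b", "t2", 1)]))
        assert mean_shortest_path(net) == pytest.approx(1.0)


class TestDensity:
    def test_complete_graph(self):
        assert density(from_graph(nx.complete_graph(4))) == pytest.approx(1.0)

    def test_star_six_nodes(self):
        assert density(star(5)) == pytest.approx(1 / 3)

    def test_equals_mean_degree_over_n_minus_one(self):
        edges, _ = gen_interaction_network(GeneratorConfig(seed=4, n_compounds=80, n_targets=25))
        net = build_network(edges)
        stats = network_stats(net)
        n = stats.n_compounds + stats.n_targets
        assert stats.density == pytest.approx(stats.mean_degree / (n - 1))


# ---------------------------------------------------------------------------
# scale-free fit
# ---------------------------------------------------------------------------

class TestFitPowerLaw:
    def test_exact_histogram_recovers_exponent(self):
        seq = []
        for k in range(1, 21):
            seq.extend([k] * int(round(1000 * k ** -2.0)))
        fit = fit_power_law(seq)
        assert fit.gamma == pytest.approx(-2.0, abs=0.05)
        assert fit.r < -0.99

    def test_uniform_degrees_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_power_law([4] * 50)

    def test_exponent_recovery_on_configuration_model(self):
        cfg = GeneratorConfig(seed=5, n_compounds=2000, n_targets=250, degree_exponent=1.5)
        edges, truth = gen_interaction_network(cfg)
        fit = fit_power_law(truth["compound_degrees"])
        assert -fit.gamma == pytest.approx(1.5, abs=0.15)
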