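"""Correlation graph filters, Prim MST vs enumeration, communities, augmentation."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from methsubtype.network import (
    GeneNetwork,
    NetworkParams,
    augment_clusters,
    build_graph,
    communities,
    correlation_matrix,
    minimum_spanning_tree,
)


def r_matrix(edges, genes):
    r = pd.DataFrame(np.eye(len(genes)), index=genes, columns=genes)
    for a, b, v in edges:
        r.loc[a, b] = r.loc[b, a] = v
    return r


def brute_force_mst_weight(graph: nx.Graph) -> float:
    """Minimal spanning-tree weight by enumeration over all edge subsets."""
    nodes = list(graph.nodes)
    edges = list(graph.edges(data="weight"))
    best = np.inf
    for subset in itertools.combinations(edges, len(nodes) - 1):
        t = nx.Graph()
        t.add_nodes_from(nodes)
        t.add_weighted_edges_from(subset)
        if nx.is_connected(t):
            best = min(best, sum(w for _, _, w in subset))
    return best


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self, rng):
        values = pd.DataFrame(rng.normal(size=(4, 10)),
                              index=["a", "b", "c", "d"])
        r = correlation_matrix(values)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_exact_negation_minus_one(self, rng):
        x = rng.normal(size=10)
        values = pd.DataFrame([x, -x], index=["g", "neg"])
        r = correlation_matrix(values)
        assert r.loc["g", "neg"] == pytest.approx(-1.0)

    def test_three_gene_hand_computation(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 5.0], [3.0, 1.0, 2.0]],
            index=["a", "b", "c"],
        )
        r = correlation_matrix(values)

        def pearson(x, y):
            x, y = np.asarray(x, float), np.asarray(y, float)
            xc, yc = x - x.mean(), y - y.mean()
            return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))

        for a, b in [("a", "b"), ("a", "c"), ("b", "c")]:
            assert r.loc[a, b] == pytest.approx(pearson(values.loc[a], values.loc[b]))

    def test_constant_gene_excluded_with_warning(self, rng):
        values = pd.DataFrame(
            np.vstack([rng.normal(size=(2, 8)), np.ones(8)]),
            index=["a", "b", "flat"],
        )
        with pytest.warns(UserWarning, match="constant"):
            r = correlation_matrix(values)
        assert "flat" not in r.index

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(pd.DataFrame([[1.0, 2.0]], index=["a"]))


class TestBuildGraph:
    def test_edge_at_exact_threshold_removed(self):
        r = r_matrix(
            [("a", "b", 0.6), ("a", "c", 0.9), ("b", "c", 0.9), ("a", "d", 0.9),
             ("b", "d", 0.9)],
            ["a", "b", "c", "d"],
        )
        g = build_graph(r, pd.Series(0.5, index=r.index))
        assert not g.graph.has_edge("a", "b")

    def test_low_degree_vertex_removed(self):
        # d hangs on a single edge -> removed by the degree filter
        r = r_matrix(
            [("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", 0.9), ("c", "d", 0.9)],
            ["a", "b", "c", "d"],
        )
        g = build_graph(r, pd.Series(0.5, index=r.index))
        assert "d" not in g.genes
        assert set(g.genes) == {"a", "b", "c"}

    def test_triangle_retained_with_sizes(self):
        r = r_matrix([("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", 0.9)],
                     ["a", "b", "c"])
        means = pd.Series({"a": 0.3, "b": 0.5, "c": 0.7})
        g = build_graph(r, means)
        assert g.graph.number_of_edges() == 3
        assert g.graph.nodes["b"]["size"] == pytest.approx(5.0)

    def test_filter_invariants_on_random_input(self, rng):
        values = pd.DataFrame(rng.normal(size=(15, 20)),
                              index=[f"g{i}" for i in range(15)])
        r = correlation_matrix(values)
        params = NetworkParams(r_threshold=0.2, min_degree=2)
        g = build_graph(r, values.mean(axis=1), params)
        for _, _, data in g.graph.edges(data=True):
            assert data["r"] > 0.2
        # single-pass degree filter: no vertex had degree < 2 at prune time
        full = build_graph(r, values.mean(axis=1),
                           NetworkParams(r_threshold=0.2, min_degree=0))
        for v in g.genes:
            assert full.graph.degree(v) >= 2

    def test_empty_result_warns(self):
        r = r_matrix([("a", "b", 0.1)], ["a", "b"])
        with pytest.warns(UserWarning, match="empty"):
            g = build_graph(r, pd.Series(0.5, index=r.index))
        assert g.graph.number_of_nodes() == 0


class TestMinimumSpanningTree:
    def _network(self, edges, genes):
        g = nx.Graph()
        for a, b, r in edges:
            g.add_edge(a, b, r=r, weight=1.0 - r)
        for v in genes:
            g.add_node(v, mean_beta=0.5, size=5.0)
        return GeneNetwork(graph=g)

    def test_triangle_keeps_two_strongest_edges(self):
        net = self._network(
            [("a", "b", 0.9), ("b", "c", 0.8), ("a", "c", 0.7)], ["a", "b", "c"]
        )
        tree = minimum_spanning_tree(net)
        kept = {frozenset(e) for e in tree.graph.edges}
        assert kept == {frozenset({"a", "b"}), frozenset({"b", "c"})}

    def test_tree_input_unchanged(self):
        net = self._network([("a", "b", 0.9), ("b", "c", 0.8)], ["a", "b", "c"])
        tree = minimum_spanning_tree(net)
        assert set(tree.graph.edges) == set(net.graph.edges)

    def test_matches_enumeration_on_random_graphs(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 7))
            g = nx.gnp_random_graph(n, 0.7, seed=int(rng.integers(0, 2**31)))
            if not nx.is_connected(g):
                continue
            for a, b in g.edges:
                r = float(rng.uniform(-0.5, 0.99))
                g[a][b]["r"] = r
                g[a][b]["weight"] = 1.0 - r
            net = GeneNetwork(graph=g)
            tree = minimum_spanning_tree(net)
            weight = sum(d["weight"] for _, _, d in tree.graph.edges(data=True))
            assert weight == pytest.approx(brute_force_mst_weight(g))

    def test_disconnected_input_gives_forest(self):
        net = self._network(
            [("a", "b", 0.9), ("c", "d", 0.8)], ["a", "b", "c", "d"]
        )
        tree = minimum_spanning_tree(net)
        assert tree.graph.number_of_edges() == 2  # n - #components = 4 - 2


class TestCommunities:
    def _two_triangles(self):
        g = nx.Graph()
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]:
            g.add_edge(a, b, r=0.9, weight=0.1)
        return GeneNetwork(graph=g)

    def test_two_triangles_split_at_bridge(self):
        assignment = communities(self._two_triangles())
        assert assignment[0] == assignment[1] == assignment[2]
        assert assignment[3] == assignment[4] == assignment[5]
        assert assignment[0] != assignment[3]

    def test_matches_modularity_enumeration(self):
        """The returned partition attains the best modularity among all
        partitions reachable by edge removals — cross-checked against the
        global optimum over every partition of the 6 vertices."""
        from itertools import combinations

        net = self._two_triangles()
        g = net.graph
        assignment = communities(net)

        def partitions(collection):
            if len(collection) == 1:
                yield [collection]
                return
            first = collection[0]
            for smaller in partitions(collection[1:]):
                for i, subset in enumerate(smaller):
                    yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
                yield [[first]] + smaller

        best_q = max(
            nx.algorithms.community.modularity(g, [set(p) for p in part])
            for part in partitions(list(g.nodes))
        )
        got = {}
        for v, c in assignment.items():
            got.setdefault(c, set()).add(v)
        q = nx.algorithms.community.modularity(g, list(got.values()))
        assert q == pytest.approx(best_q)

    def test_disconnected_components_separate(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.1)
        g.add_edge("c", "d", weight=0.1)
        assignment = communities(GeneNetwork(graph=g))
        assert assignment["a"] == assignment["b"]
        assert assignment["c"] == assignment["d"]
        assert assignment["a"] != assignment["c"]

    def test_complete_graph_single_community(self):
        g = nx.complete_graph(5)
        assignment = communities(GeneNetwork(graph=g))
        assert len(set(assignment.values())) == 1

    def test_partition_covers_all_vertices(self, rng):
        g = nx.gnp_random_graph(10, 0.4, seed=7)
        assignment = communities(GeneNetwork(graph=g))
        assert set(assignment) == set(g.nodes)


class TestAugmentClusters:
    def test_perfect_cluster_unchanged(self):
        calls = []

        def train_eval(genes):
            calls.append(list(genes))
            return pd.Series(1.0, index=["W", "S", "G3", "G4"])

        out, trace = augment_clusters({"c1": ["g1", "g2"]}, ["g3", "g4"],
                                      train_eval)
        assert out == {"c1": ["g1", "g2"]}
        assert len(calls) == 1  # baseline only; no trials needed

    def test_discriminating_gene_added(self):
        # macro F1 jumps only when the marker gene joins the set
        def train_eval(genes):
            good = 1.0 if "marker" in genes else 0.5
            return pd.Series([good, 1.0], index=["A", "B"])

        out, trace = augment_clusters(
            {"c1": ["g1"]}, ["noise", "marker"], train_eval, min_gain=0.01
        )
        assert "marker" in out["c1"]
        assert not trace[trace["candidate"] == "noise"]["accepted"].any()

    def test_unreachable_gain_blocks_all(self):
        def train_eval(genes):
            return pd.Series([0.5 + 0.01 * len(genes)], index=["A"])

        out, _ = augment_clusters({"c1": ["g1"]}, ["g2", "g3"], train_eval,
                                  min_gain=1.5)
        assert out == {"c1": ["g1"]}

    def test_overlapping_clusters_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            augment_clusters({"a": ["g1"], "b": ["g1"]}, [], lambda g: pd.Series([1.0]))

    def test_eval_failure_aborts_with_message(self):
        def train_eval(genes):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="trace preserved"):
            augment_clusters({"a": ["g1"]}, [], train_eval)
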