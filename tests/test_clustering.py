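import itertools
import math

import numpy as np
import pytest

from conftest import random_graph
from oracles import oracle_edge_betweenness
from bionet3d import fixtures as fix
from bionet3d.clustering import (
    MCLParams,
    cluster_girvan_newman,
    cluster_leading_eigenvector,
    cluster_mcl,
    edge_betweenness,
    modularity,
)
from bionet3d.graph_core import Edge, Graph, Partition


def _canon(partition: Partition) -> frozenset:
    return frozenset(frozenset(c) for c in partition.clusters())


def _two_triangles() -> Graph:
    g = Graph()
    for u, v in [("a", "b"), ("b", "c"), ("c", "a"), ("x", "y"), ("y", "z"), ("z", "x")]:
        g.add_edge(Edge(u, v))
    return g


class TestEdgeBetweenness:
    def test_barbell_bridge_carries_all_cross_pairs(self, barbell):
        g, _ = barbell
        eb = edge_betweenness(g)
        assert eb[("a2", "b0")] == pytest.approx(9.0)  # 3x3 cross pairs

    def test_single_edge(self):
        g = Graph()
        g.add_edge(Edge("a", "b"))
        assert edge_betweenness(g)[("a", "b")] == pytest.approx(1.0)

    def test_four_cycle_symmetric(self):
        g = fix.make_classic("cycle", 4)
        vals = set(round(v, 9) for v in edge_betweenness(g).values())
        assert len(vals) == 1

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            g = random_graph(rng, int(rng.integers(2, 9)), weighted=bool(rng.integers(0, 2)))
            got = edge_betweenness(g)
            want = oracle_edge_betweenness(g)
            for key in want:
                assert got[key] == pytest.approx(want[key], abs=1e-9), key


class TestModularity:
    def test_single_cluster_is_zero(self, triangle):
        part = Partition({nid: 0 for nid in triangle.node_ids})
        assert modularity(triangle, part) == pytest.approx(0.0)

    def test_two_disjoint_triangles_maximum_half(self):
        g = _two_triangles()
        best = Partition.from_sets([{"a", "b", "c"}, {"x", "y", "z"}])
        assert modularity(g, best) == pytest.approx(0.5)
        # brute force over every 2-label assignment: 0.5 is the maximum
        ids = sorted(g.node_ids)
        for labels in itertools.product([0, 1], repeat=len(ids)):
            q = modularity(g, Partition(dict(zip(ids, labels))))
            assert q <= 0.5 + 1e-12
        shuffled = Partition.from_sets([{"a", "b", "x"}, {"c", "y", "z"}])
        assert modularity(g, shuffled) < 0.5

    def test_edgeless_graph_undefined(self):
        g = Graph()
        g.add_node("a")
        with pytest.raises(ValueError):
            modularity(g, Partition({"a": 0}))


class TestGirvanNewman:
    def test_barbell_removes_bridge_first(self, barbell):
        g, truth = barbell
        trace = cluster_girvan_newman(g)
        assert trace.removed_edges[0][0] == ("a2", "b0")
        assert _canon(trace.best_partition) == _canon(truth)
        assert trace.best_modularity == pytest.approx(modularity(g, trace.best_partition))

    def test_pendant_edge_protected(self):
        g = fix.make_classic("cycle", 3)
        g.add_edge(Edge("n0", "p"))  # pendant
        trace = cluster_girvan_newman(g, removal_fraction=1.0)
        assert ("n0", "p") not in [e for e, _ in trace.removed_edges]

    def test_star_nothing_removable(self):
        g = fix.make_classic("star", 6)
        trace = cluster_girvan_newman(g)
        assert trace.removed_edges == []
        assert trace.best_partition.k == 1

    def test_budget_is_ceil_fraction_of_m(self):
        g = fix.make_classic("cycle", 10)
        trace = cluster_girvan_newman(g, removal_fraction=0.2)
        assert len(trace.removed_edges) == math.ceil(0.2 * 10)

    def test_invalid_fraction(self, triangle):
        with pytest.raises(ValueError):
            cluster_girvan_newman(triangle, removal_fraction=1.5)

    def test_best_q_at_least_component_partition(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            g = random_graph(rng, int(rng.integers(3, 9)))
            from bionet3d.graph_core import connected_components

            base = Partition.from_sets(connected_components(g))
            trace = cluster_girvan_newman(g)
            assert trace.best_modularity >= modularity(g, base) - 1e-12


class TestMCL:
    def test_barbell_two_triangles(self, barbell):
        g, truth = barbell
        part, converged = cluster_mcl(g, MCLParams(inflation=2.0))
        assert converged
        assert _canon(part) == _canon(truth)

    def test_matches_independent_dense_fixed_point(self, barbell):
        """Sparse implementation vs a from-scratch dense NumPy iteration."""
        g, _ = barbell
        order = sorted(g.node_ids)
        idx = {v: i for i, v in enumerate(order)}
        n = len(order)
        a = np.zeros((n, n))
        for e in g.edges:
            i, j = idx[e.source], idx[e.target]
            a[i, j] = a[j, i] = e.weight
        np.fill_diagonal(a, 1.0)
        m = a / a.sum(axis=0)
        for _ in range(200):
            prev = m.copy()
            m = m @ m
            m = m**2.0
            m = m / m.sum(axis=0)
            m[m < 1e-5] = 0.0
            s = m.sum(axis=0)
            s[s == 0] = 1.0
            m = m / s
            if np.abs(m - prev).max() < 1e-6:
                break
        import scipy.sparse as sp

        _, labels = sp.csgraph.connected_components(sp.csr_matrix((m + m.T) > 0), directed=False)
        dense_part = Partition({order[i]: int(labels[i]) for i in range(n)})
        part, _ = cluster_mcl(g, MCLParams(inflation=2.0))
        assert _canon(part) == _canon(dense_part)

    def test_no_cluster_spans_components(self):
        g = _two_triangles()
        part, _ = cluster_mcl(g)
        for cluster in part.clusters():
            assert cluster <= {"a", "b", "c"} or cluster <= {"x", "y", "z"}

    def test_single_node(self):
        g = Graph()
        g.add_node("a")
        part, converged = cluster_mcl(g)
        assert part.membership == {"a": 0} and converged

    def test_column_stochastic_preserved(self):
        # the normalization helper keeps every column summing to 1
        from bionet3d.clustering import _column_normalize
        import scipy.sparse as sp

        rng = np.random.default_rng(41)
        mat = sp.random(30, 30, density=0.2, random_state=np.random.RandomState(41), format="csr")
        mat = _column_normalize(mat + sp.eye(30).tocsr())
        for _ in range(5):
            mat = _column_normalize(mat.power(2.0))
            sums = np.asarray(mat.sum(axis=0)).ravel()
            assert np.allclose(sums, 1.0, atol=1e-9)

    def test_inflation_monotone_cluster_count(self):
        g, _ = fix.make_modular(3, 12, 0.5, 0.02, seed=42)
        ks = []
        for inflation in (1.3, 2.0, 3.0):
            part, _ = cluster_mcl(g, MCLParams(inflation=inflation))
            ks.append(part.k)
        assert ks == sorted(ks)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            MCLParams(inflation=1.0)
        with pytest.raises(ValueError):
            MCLParams(expansion=1)


class TestLeadingEigenvector:
    def test_barbell_two_triangles(self, barbell):
        g, truth = barbell
        part = cluster_leading_eigenvector(g)
        assert _canon(part) == _canon(truth)
        # cross-check the split against the dense 6x6 modularity matrix
        order = sorted(g.node_ids)
        idx = {v: i for i, v in enumerate(order)}
        a = np.zeros((6, 6))
        for e in g.edges:
            i, j = idx[e.source], idx[e.target]
            a[i, j] = a[j, i] = 1.0
        deg = a.sum(axis=1)
        b = a - np.outer(deg, deg) / deg.sum()
        lead = np.linalg.eigh(b)[1][:, -1]
        oracle = frozenset(
            (
                frozenset(order[i] for i in range(6) if lead[i] >= 0),
                frozenset(order[i] for i in range(6) if lead[i] < 0),
            )
        )
        assert _canon(part) == oracle

    def test_complete_graph_single_cluster(self):
        g = fix.make_classic("clique", 5)
        part = cluster_leading_eigenvector(g)
        assert part.k == 1
        # brute force: no bipartition of K5 has positive modularity
        ids = sorted(g.node_ids)
        for labels in itertools.product([0, 1], repeat=5):
            if len(set(labels)) < 2:
                continue
            assert modularity(g, Partition(dict(zip(ids, labels)))) <= 1e-12

    def test_heavy_bridge_output_maximizes_q(self):
        g, truth = fix.make_barbell(3, bridge_weight=100.0)
        part = cluster_leading_eigenvector(g)
        q_got = modularity(g, part)
        candidates = [
            Partition({nid: 0 for nid in g.node_ids}),
            Partition.from_sets(truth.clusters()),
        ]
        assert q_got >= max(modularity(g, c) for c in candidates) - 1e-12

    def test_agrees_with_igraph_on_random_graphs(self):
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(51)
        agree = 0
        total = 0
        for _ in range(15):
            g = random_graph(rng, int(rng.integers(4, 10)))
            order = sorted(g.node_ids)
            idx = {v: i for i, v in enumerate(order)}
            ig_g = igraph.Graph(
                n=len(order), edges=[(idx[e.source], idx[e.target]) for e in g.edges]
            )
            ig_q = ig_g.modularity(ig_g.community_leading_eigenvector().membership)
            q = modularity(g, cluster_leading_eigenvector(g))
            total += 1
            if abs(q - ig_q) < 1e-9:
                agree += 1
        # identical greedy refinements are not guaranteed, but the two
        # implementations should coincide on most small instances
        assert agree >= int(0.6 * total)


class TestPartitionCoverage:
    def test_all_algorithms_cover_v_exactly_once(self):
        rng = np.random.default_rng(61)
        for _ in range(8):
            g = random_graph(rng, int(rng.integers(3, 9)))
            parts = [
                cluster_girvan_newman(g).best_partition,
                cluster_mcl(g)[0],
                cluster_leading_eigenvector(g),
            ]
            for part in parts:
                assert set(part.membership) == set(g.node_ids)
                assert sorted(set(part.membership.values())) == list(range(part.k))
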