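import math

import numpy as np
import pytest
import scipy.linalg

from conftest import random_connected_graph
from bionet3d import fixtures as fix
from bionet3d.graph_core import Edge, Graph, Layout3D
from bionet3d.layouts import (
    AnnealSchedule,
    CoarsenParams,
    FRParams,
    HemisphereSpec,
    LinLogParams,
    SemanticParams,
    adaptive_iterations,
    assign_semantic_layers,
    coarsen,
    fr_forces,
    hemisphere_position,
    layout_annealed,
    layout_coarsened,
    layout_force_directed,
    layout_hemispherical,
    layout_hybrid,
    layout_linlog,
    layout_semantic,
    linlog_energy,
    spectral_bisect,
    sphere_point,
)


def _sep(layout, u, v):
    return float(np.linalg.norm(layout.positions[u] - layout.positions[v]))


def _mean_dist(layout, group_a, group_b=None):
    pts_a = [layout.positions[n] for n in group_a]
    if group_b is None:
        ds = [np.linalg.norm(p - q) for i, p in enumerate(pts_a) for q in pts_a[i + 1 :]]
    else:
        pts_b = [layout.positions[n] for n in group_b]
        ds = [np.linalg.norm(p - q) for p in pts_a for q in pts_b]
    return float(np.mean(ds))


class TestForces:
    def test_printed_force_formulas(self):
        assert fr_forces(2.0, 1.0) == (4.0, -0.5)
        fa, fr = fr_forces(3.0, 3.0)
        assert fa == 3.0 and fr == -3.0  # equal magnitude at equilibrium d=k

    def test_k_from_volume(self):
        assert FRParams(volume=8.0).k(1) == pytest.approx(2.0)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            fr_forces(0.0, 1.0)


class TestForceDirected:
    def test_single_node_centered(self):
        g = Graph()
        g.add_node("a")
        lay = layout_force_directed(g)
        assert np.allclose(lay.positions["a"], 0.0)

    def test_two_node_equilibrium_near_k(self):
        g = Graph()
        g.add_edge(Edge("a", "b"))
        params = FRParams(seed=1)
        lay = layout_force_directed(g, params)
        assert _sep(lay, "a", "b") == pytest.approx(params.k(2), rel=0.10)

    def test_disjoint_cliques_separate(self):
        g = Graph()
        groups = [[f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)]]
        for grp in groups:
            for i, u in enumerate(grp):
                for v in grp[i + 1 :]:
                    g.add_edge(Edge(u, v))
        lay = layout_force_directed(g, FRParams(seed=2))
        intra = (_mean_dist(lay, groups[0]) + _mean_dist(lay, groups[1])) / 2.0
        inter = _mean_dist(lay, groups[0], groups[1])
        assert intra < inter

    def test_positions_inside_volume_and_finite(self):
        g = fix.make_scale_free(40, 2, seed=3)
        params = FRParams(seed=3)
        lay = layout_force_directed(g, params)
        pts = np.array(list(lay.positions.values()))
        assert np.all(np.isfinite(pts))
        assert np.all(np.abs(pts) <= params.side() / 2.0 + 1e-9)

    def test_deterministic_per_seed(self):
        g = fix.make_scale_free(20, 2, seed=0)
        a = layout_force_directed(g, FRParams(seed=9))
        b = layout_force_directed(g, FRParams(seed=9))
        c = layout_force_directed(g, FRParams(seed=10))
        assert all(np.array_equal(a.positions[n], b.positions[n]) for n in g.node_ids)
        assert any(not np.array_equal(a.positions[n], c.positions[n]) for n in g.node_ids)

    def test_iteration_budget_non_increasing_in_n(self):
        budgets = [adaptive_iterations(n) for n in (1, 10, 100, 1000, 10_000, 1_000_000)]
        assert budgets == sorted(budgets, reverse=True)
        assert budgets[0] == 1000 and budgets[-1] == 50


class TestLinLog:
    def test_energy_single_edge_unit_separation(self):
        g = Graph()
        g.add_edge(Edge("a", "b"))
        lay = Layout3D({"a": [0.0, 0.0, 0.0], "b": [1.0, 0.0, 0.0]})
        e = linlog_energy(lay, g, LinLogParams(r=1.0))
        assert e == pytest.approx(1.0)  # 1 - ln 1

    def test_energy_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        g = fix.make_classic("path", 3)
        pos = {nid: rng.normal(size=3) for nid in g.node_ids}
        lay = Layout3D(pos)
        for mode in ("node-repulsion", "edge-repulsion"):
            params = LinLogParams(r=1.7, mode=mode)
            # independent double-loop sum
            ids = sorted(g.node_ids)
            attract = sum(
                np.linalg.norm(np.asarray(pos[e.source]) - np.asarray(pos[e.target])) ** 1.7 / 1.7
                for e in g.edges
            )
            rep = 0.0
            for i, u in enumerate(ids):
                for v in ids[i + 1 :]:
                    w = 1.0 if mode == "node-repulsion" else g.degree(u) * g.degree(v)
                    rep += w * math.log(np.linalg.norm(np.asarray(pos[u]) - np.asarray(pos[v])))
            assert linlog_energy(lay, g, params) == pytest.approx(attract - rep, abs=1e-9)

    def test_coincident_nodes_rejected(self):
        g = Graph()
        g.add_edge(Edge("a", "b"))
        lay = Layout3D({"a": [0.0, 0.0, 0.0], "b": [0.0, 0.0, 0.0]})
        with pytest.raises(ValueError, match="jitter"):
            linlog_energy(lay, g, LinLogParams())

    def test_single_edge_equilibria(self):
        # d - ln d minimized at d=1; (1/3)d^3 - ln d also minimized at d=1
        g = Graph()
        g.add_edge(Edge("a", "b"))
        for r in (1.0, 3.0):
            lay = layout_linlog(g, LinLogParams(r=r, seed=5))
            assert _sep(lay, "a", "b") == pytest.approx(1.0, rel=0.05)

    def test_r3_matches_fr_equilibrium(self):
        # with volume = n the FR equilibrium length k is 1, same as 3-PolyLog
        g = Graph()
        g.add_edge(Edge("a", "b"))
        fr = layout_force_directed(g, FRParams(volume=2.0, seed=6))
        ll = layout_linlog(g, LinLogParams(r=3.0, seed=6))
        assert _sep(ll, "a", "b") == pytest.approx(_sep(fr, "a", "b"), rel=0.05)

    def test_cliques_cut_distance_exceeds_intra(self):
        g = Graph()
        groups = [[f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]]
        for grp in groups:
            for i, u in enumerate(grp):
                for v in grp[i + 1 :]:
                    g.add_edge(Edge(u, v))
        lay = layout_linlog(g, LinLogParams(r=1.0, seed=7))
        intra = max(_mean_dist(lay, groups[0]), _mean_dist(lay, groups[1]))
        assert _mean_dist(lay, groups[0], groups[1]) > intra


class TestSpectralBisect:
    def test_path_splits_in_half(self):
        g = fix.make_classic("path", 4)
        res = spectral_bisect(g)
        assert {frozenset(res.part_a), frozenset(res.part_b)} == {
            frozenset({"n0", "n1"}),
            frozenset({"n2", "n3"}),
        }

    def test_barbell_cuts_the_bridge(self, barbell):
        g, truth = barbell
        # brute-force minimum balanced cut over all 2^6 sign vectors
        import itertools

        ids = sorted(g.node_ids)
        best_cut, best_parts = math.inf, None
        for signs in itertools.product([1, -1], repeat=len(ids)):
            if abs(sum(signs)) > 0:
                continue
            a = {nid for nid, s in zip(ids, signs) if s > 0}
            cut = sum(1 for e in g.edges if (e.source in a) != (e.target in a))
            if cut < best_cut:
                best_cut, best_parts = cut, {frozenset(a), frozenset(set(ids) - a)}
        res = spectral_bisect(g)
        assert {frozenset(res.part_a), frozenset(res.part_b)} == best_parts
        assert best_cut == 1

    def test_matches_dense_eigensolver_on_random_graphs(self):
        """Power-iteration Fiedler vector vs scipy dense eigendecomposition."""
        rng = np.random.default_rng(11)
        from bionet3d.layouts import _laplacian

        for _ in range(40):
            g = random_connected_graph(rng, int(rng.integers(2, 11)))
            order = sorted(g.node_ids)
            eigvals, eigvecs = scipy.linalg.eigh(_laplacian(g, order))
            res = spectral_bisect(g)
            assert res.eigenvalue == pytest.approx(eigvals[1], abs=1e-6)
            assert abs(sum(res.q.values())) <= 1  # balanced split
            gap = eigvals[2] - eigvals[1] if len(eigvals) > 2 else 1.0
            if gap > 1e-6:  # non-degenerate: the direction itself is unique
                cosine = abs(float(res.fiedler @ eigvecs[:, 1]))
                assert cosine > 0.999

    def test_disconnected_rejected(self):
        g = Graph()
        g.add_node("a")
        g.add_node("b")
        with pytest.raises(ValueError, match="disconnected|2 nodes"):
            spectral_bisect(g)


class TestHybrid:
    def test_parts_do_not_overlap(self):
        g = fix.make_classic("path", 4)
        lay = layout_hybrid(g, FRParams(seed=1))
        res = spectral_bisect(g)
        pts_a = np.array([lay.positions[n] for n in res.part_a])
        pts_b = np.array([lay.positions[n] for n in res.part_b])
        assert pts_a[:, 0].max() < pts_b[:, 0].min() or pts_b[:, 0].max() < pts_a[:, 0].min()

    def test_single_node(self):
        g = Graph()
        g.add_node("a")
        assert np.allclose(layout_hybrid(g).positions["a"], 0.0)

    def test_barbell_triangles_in_separate_half_spaces(self, barbell):
        g, truth = barbell
        lay = layout_hybrid(g, FRParams(seed=2))
        left, right = truth.clusters()
        xs_l = [lay.positions[n][0] for n in left]
        xs_r = [lay.positions[n][0] for n in right]
        assert max(xs_l) < min(xs_r) or max(xs_r) < min(xs_l)


class TestCoarsen:
    def test_triangle_no_coarsening(self, triangle):
        levels = coarsen(triangle)
        assert len(levels) == 1

    def test_path_levels_strictly_decrease(self):
        g = fix.make_classic("path", 8)
        levels = coarsen(g)
        sizes = [lvl[0].n for lvl in levels]
        assert sizes == sorted(sizes, reverse=True)
        assert len(set(sizes)) == len(sizes)

    def test_star_matching_and_rate_stop(self):
        # K1,5: heavy-edge matching can only collapse the hub with one
        # leaf per round; 6 -> 5 gives ratio 5/6 > 0.75 so coarsening stops
        g = fix.make_classic("star", 6)
        levels = coarsen(g, CoarsenParams(seed=0))
        assert len(levels) == 2
        assert levels[1][0].n == 5

    def test_projection_maps_compose(self):
        g = fix.make_scale_free(30, 2, seed=1)
        levels = coarsen(g, CoarsenParams(seed=1))
        current = {nid: nid for nid in g.node_ids}
        for _graph, proj in levels[1:]:
            current = {nid: proj[c] for nid, c in current.items()}
        coarsest_ids = set(levels[-1][0].node_ids)
        assert set(current.values()) <= coarsest_ids
        assert set(current) == set(g.node_ids)


class TestCoarsenedLayout:
    def test_below_min_size_equals_plain_fr(self, triangle):
        a = layout_coarsened(triangle, CoarsenParams(), FRParams(seed=4))
        b = layout_force_directed(triangle, FRParams(seed=4))
        assert all(np.allclose(a.positions[n], b.positions[n]) for n in triangle.node_ids)

    def test_disjoint_cliques_separate(self):
        g = Graph()
        groups = [[f"a{i}" for i in range(6)], [f"b{i}" for i in range(6)]]
        for grp in groups:
            for i, u in enumerate(grp):
                for v in grp[i + 1 :]:
                    g.add_edge(Edge(u, v))
        lay = layout_coarsened(g, CoarsenParams(seed=5), FRParams(seed=5))
        intra = (_mean_dist(lay, groups[0]) + _mean_dist(lay, groups[1])) / 2.0
        assert intra < _mean_dist(lay, groups[0], groups[1])

    def test_stress_within_2x_of_direct_fr(self):
        g, _ = fix.make_modular(4, 50, 0.2, 0.01, seed=6)
        params = FRParams(seed=6)
        order = sorted(g.node_ids)
        from bionet3d.layouts import _net_forces

        def stress(lay):
            index = {nid: i for i, nid in enumerate(order)}
            pos = lay.as_array(order)
            edges_idx = np.array([[index[e.source], index[e.target]] for e in g.edges])
            net = _net_forces(pos, edges_idx, params.k(g.n))
            return float(np.sum(np.linalg.norm(net, axis=1)))

        s_coarse = stress(layout_coarsened(g, CoarsenParams(seed=6), params))
        s_direct = stress(layout_force_directed(g, params))
        assert s_coarse <= 2.0 * s_direct


class TestAnnealed:
    def test_edge_cut_zero_reproduces_fr(self, triangle):
        a = layout_annealed(triangle, AnnealSchedule(edge_cut=0.0, seed=3))
        b = layout_force_directed(triangle, FRParams(seed=3))
        for n in triangle.node_ids:
            assert np.allclose(a.positions[n], b.positions[n], atol=1e-9)

    def test_edge_cut_separates_cliques_more(self):
        g = Graph()
        groups = [[f"a{i}" for i in range(8)], [f"b{i}" for i in range(8)]]
        for grp in groups:
            for i, u in enumerate(grp):
                for v in grp[i + 1 :]:
                    g.add_edge(Edge(u, v))
        g.add_edge(Edge("a7", "b0"))

        def ratio(lay):
            intra = (_mean_dist(lay, groups[0]) + _mean_dist(lay, groups[1])) / 2.0
            inter = _mean_dist(lay, groups[0], groups[1])
            return inter / intra

        r_cut = ratio(layout_annealed(g, AnnealSchedule(edge_cut=0.8, seed=8)))
        r_plain = ratio(layout_annealed(g, AnnealSchedule(edge_cut=0.0, seed=8)))
        assert r_cut > r_plain

    def test_empty_graph_and_bad_edge_cut(self):
        assert layout_annealed(Graph()).positions == {}
        with pytest.raises(ValueError):
            AnnealSchedule(edge_cut=1.5)


class TestSemanticLayers:
    def test_user_layers_pass_through(self, triangle):
        user = {"n0": 0, "n1": 1, "n2": 2}
        got = assign_semantic_layers(triangle, SemanticParams(n_layers=3, user_layers=user))
        assert got == user

    def test_user_layer_out_of_range(self, triangle):
        with pytest.raises(ValueError):
            assign_semantic_layers(
                triangle, SemanticParams(n_layers=2, user_layers={"n0": 5, "n1": 0, "n2": 0})
            )

    def test_star_hub_alone_in_top_layer(self):
        g = fix.make_classic("star", 10)  # K1,9
        layers = assign_semantic_layers(g, SemanticParams(n_layers=2))
        assert layers["n0"] == 0
        assert all(layers[f"n{i}"] == 1 for i in range(1, 10))

    def test_regular_ring_equal_bins_by_id(self):
        g = fix.make_classic("cycle", 14)
        layers = assign_semantic_layers(g, SemanticParams(n_layers=7))
        counts = [list(layers.values()).count(j) for j in range(7)]
        assert counts == [2] * 7
        ranked = sorted(g.node_ids)
        assert [layers[nid] for nid in ranked] == sorted(layers[nid] for nid in ranked)

    def test_z_values_exactly_layer_times_spacing(self):
        g = fix.make_scale_free(12, 2, seed=9)
        lay = layout_semantic(g, SemanticParams(n_layers=3, spacing=10.0, seed=9))
        zs = {float(p[2]) for p in lay.positions.values()}
        assert zs <= {0.0, 10.0, 20.0}

    def test_default_seven_distinct_levels(self):
        g = fix.make_scale_free(30, 2, seed=10)
        lay = layout_semantic(g, SemanticParams(seed=10))
        assert len({float(p[2]) for p in lay.positions.values()}) == 7

    def test_single_layer_planar(self, triangle):
        lay = layout_semantic(triangle, SemanticParams(n_layers=1))
        assert all(p[2] == 0.0 for p in lay.positions.values())


class TestHemisphere:
    def test_printed_trig_formulas(self):
        assert np.allclose(sphere_point(90.0, 0.0, 1.0), [0.0, 0.0, 1.0], atol=1e-12)
        assert np.allclose(sphere_point(0.0, 0.0, 2.0), [2.0, 0.0, 0.0], atol=1e-12)
        assert np.allclose(sphere_point(0.0, 90.0, 1.0), [0.0, 1.0, 0.0], atol=1e-12)

    def test_rank0_exactly_at_pole(self):
        spec = HemisphereSpec(R=3.0, center=(1.0, 2.0, 3.0))
        assert np.array_equal(hemisphere_position(0, 5, spec), np.array([1.0, 2.0, 6.0]))

    def test_rank_out_of_range(self):
        with pytest.raises(ValueError):
            hemisphere_position(5, 5)

    def test_star_hub_at_pole_and_surface_invariant(self):
        g = fix.make_classic("star", 7)
        spec = HemisphereSpec(R=10.0)
        lay = layout_hemispherical(g, spec)
        assert np.allclose(lay.positions["n0"], [0.0, 0.0, 10.0])
        for p in lay.positions.values():
            assert abs(np.linalg.norm(p) - 10.0) < 1e-9
            assert p[2] >= -1e-12  # upper hemisphere

    def test_min_gap_near_equal_area_ideal(self):
        from scipy.spatial.distance import pdist

        n = 100
        pts = np.array([hemisphere_position(i, n, HemisphereSpec(R=1.0)) for i in range(n)])
        min_gap = pdist(pts).min()
        ideal = math.sqrt(2.0 * math.pi / n)  # area per node, square packing
        assert abs(min_gap - ideal) / ideal < 0.30

    def test_deterministic(self):
        g = fix.make_scale_free(15, 2, seed=0)
        a = layout_hemispherical(g)
        b = layout_hemispherical(g)
        assert all(np.array_equal(a.positions[n], b.positions[n]) for n in g.node_ids)
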