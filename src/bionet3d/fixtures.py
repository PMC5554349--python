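"""Seeded synthetic-network generators.

These emulate the shapes biomolecular networks take in practice —
modular (planted communities), scale-free (hubs from preferential
attachment), layered (gene/disease/drug style multi-type graphs), and
coordinate-pinned (physically constrained networks built from a
distance-decaying correlation structure, as in residue-contact data) —
plus the small classic graphs (path, star, cycle, clique, barbell) every
algorithm test leans on.  Identical parameters + seed give identical
graphs.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np

from .graph_core import Edge, Graph, Partition

__all__ = [
    "make_classic",
    "make_barbell",
    "make_modular",
    "make_scale_free",
    "make_layered",
    "make_coordinate_pinned",
]


def _from_networkx(g: nx.Graph) -> Graph:
    out = Graph()
    for nid in sorted(g.nodes, key=str):
        out.add_node(f"n{nid}" if not isinstance(nid, str) else nid)
    for u, v, data in g.edges(data=True):
        su = f"n{u}" if not isinstance(u, str) else u
        sv = f"n{v}" if not isinstance(v, str) else v
        out.add_edge(Edge(su, sv, float(data.get("weight", 1.0))))
    return out


def make_classic(family: str, n: int) -> Graph:
    """path | star | cycle | clique on n nodes (ids n0..n{n-1})."""
    builders = {
        "path": nx.path_graph,
        "star": lambda n: nx.star_graph(n - 1),
        "cycle": nx.cycle_graph,
        "clique": nx.complete_graph,
    }
    if family not in builders:
        raise ValueError(f"unknown classic family {family!r}")
    return _from_networkx(builders[family](n))


def make_barbell(clique_size: int = 3, *, bridge_weight: float = 1.0) -> tuple[Graph, Partition]:
    """Two cliques joined by a single bridge edge, plus the planted
    2-community partition."""
    g = Graph()
    left = [f"a{i}" for i in range(clique_size)]
    right = [f"b{i}" for i in range(clique_size)]
    for group in (left, right):
        for u, v in combinations(group, 2):
            g.add_edge(Edge(u, v))
    g.add_edge(Edge(left[-1], right[0], bridge_weight))
    return g, Partition.from_sets([left, right])


def make_modular(
    k: int, size: int, p_in: float, p_out: float, seed: int = 0
) -> tuple[Graph, Partition]:
    """Planted-partition graph: k communities of equal size, edge
    probability p_in within and p_out between communities."""
    if not (0.0 <= p_out < p_in <= 1.0) and not (p_in == p_out == 0.0):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    g = Graph()
    ids = [[f"c{c}_{i}" for i in range(size)] for c in range(k)]
    for group in ids:
        for nid in group:
            g.add_node(nid)
    for c, group in enumerate(ids):
        for u, v in combinations(group, 2):
            if rng.random() < p_in:
                g.add_edge(Edge(u, v))
    for c1 in range(k):
        for c2 in range(c1 + 1, k):
            for u in ids[c1]:
                for v in ids[c2]:
                    if rng.random() < p_out:
                        g.add_edge(Edge(u, v))
    return g, Partition.from_sets(ids)


def make_scale_free(n: int, m_per: int = 2, seed: int = 0) -> Graph:
    """Preferential-attachment (Barabasi-Albert) graph: connected, with
    a heavy-tailed degree distribution (a few hubs, many leaves)."""
    if n < m_per or m_per < 1:
        raise ValueError("need n >= m_per >= 1")
    return _from_networkx(nx.barabasi_albert_graph(n, m_per, seed=seed))


def make_layered(
    layer_sizes: list[int],
    within_density: float = 0.2,
    between_density: float = 0.1,
    seed: int = 0,
) -> tuple[Graph, dict[str, int]]:
    """Multi-type graph: nodes carry a layer index (e.g. gene/disease/
    drug); edges drawn independently within and between adjacent-or-any
    layer pairs at the given densities."""
    for d in (within_density, between_density):
        if not (0.0 <= d <= 1.0):
            raise ValueError("densities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = Graph()
    layers: dict[str, int] = {}
    ids: list[list[str]] = []
    for li, sz in enumerate(layer_sizes):
        group = [f"L{li}_{i}" for i in range(sz)]
        ids.append(group)
        for nid in group:
            node = g.add_node(nid)
            node.layer = li
            layers[nid] = li
    for group in ids:
        for u, v in combinations(group, 2):
            if rng.random() < within_density:
                g.add_edge(Edge(u, v))
    for g1 in range(len(ids)):
        for g2 in range(g1 + 1, len(ids)):
            for u in ids[g1]:
                for v in ids[g2]:
                    if rng.random() < between_density:
                        g.add_edge(Edge(u, v))
    return g, layers


def make_coordinate_pinned(
    n: int, corr_length: float = 2.0, top_k: int | None = None, seed: int = 0
) -> tuple[Graph, dict[str, tuple[float, float, float]]]:
    """Physically constrained network: points along a noisy 3D helix
    (tube-like region), a distance-decaying synthetic correlation
    matrix, and edges on the top-K correlated pairs."""
    max_pairs = n * (n - 1) // 2
    top_k = max_pairs // 10 if top_k is None else top_k
    if top_k > max_pairs:
        raise ValueError(f"top_k={top_k} exceeds the {max_pairs} node pairs")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 4.0 * math.pi, n)
    pts = np.column_stack([3.0 * np.cos(t), 3.0 * np.sin(t), t]) + 0.2 * rng.standard_normal((n, 3))
    ids = [f"r{i}" for i in range(n)]
    g = Graph()
    coords: dict[str, tuple[float, float, float]] = {}
    for nid, p in zip(ids, pts):
        node = g.add_node(nid)
        node.coords = tuple(float(c) for c in p)
        coords[nid] = node.coords
    scored = []
    for i, j in combinations(range(n), 2):
        d = float(np.linalg.norm(pts[i] - pts[j]))
        corr = math.exp(-d / corr_length) * (1.0 + 0.01 * rng.standard_normal())
        scored.append((corr, ids[i], ids[j]))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    for corr, u, v in scored[:top_k]:
        g.add_edge(Edge(u, v, max(corr, 1e-6)))
    return g, coords
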