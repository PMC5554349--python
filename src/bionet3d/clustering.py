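"""Graph clustering: edge-betweenness (Girvan-Newman) sweep, Markov
clustering, and leading-eigenvector modularity clustering, plus the
modularity score Q they optimize or report.

Edge weights are interpreted as path lengths for shortest-path-based
quantities (set ``weight_as_similarity=True`` to invert weights first
when larger weight means stronger interaction), and as interaction
strength in Q and in the Markov flow matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import scipy.sparse as sp

from .graph_core import Graph, Partition, connected_components

__all__ = [
    "EBCTrace",
    "MCLParams",
    "edge_betweenness",
    "modularity",
    "cluster_girvan_newman",
    "cluster_mcl",
    "cluster_leading_eigenvector",
]


def edge_betweenness(
    graph: Graph, *, weighted: bool = True, weight_as_similarity: bool = False
) -> dict[tuple[str, str], float]:
    """Edge betweenness: shortest-path count through each edge, with
    fractional credit when several shortest paths tie.  Each unordered
    node pair contributes once."""
    g = graph.to_networkx()
    weight = None
    if weighted and any(e.weight != 1.0 for e in graph.edges):
        weight = "weight"
        if weight_as_similarity:
            for u, v, data in g.edges(data=True):
                data["weight"] = 1.0 / data["weight"]
    eb = nx.edge_betweenness_centrality(g, normalized=False, weight=weight)
    return {(min(u, v), max(u, v)): float(val) for (u, v), val in eb.items()}


def modularity(graph: Graph, partition: Partition) -> float:
    """Newman-Girvan modularity Q = sum_c [ e_c/m - (d_c/2m)^2 ] with
    the weighted generalization (edge weight as interaction strength)."""
    m = graph.total_weight()
    if m == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    missing = set(graph.node_ids) - set(partition.membership)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    intra = np.zeros(partition.k)
    for e in graph.edges:
        cu, cv = partition.membership[e.source], partition.membership[e.target]
        if cu == cv:
            intra[cu] += e.weight
    deg = np.zeros(partition.k)
    for nid in graph.node_ids:
        deg[partition.membership[nid]] += graph.weighted_degree(nid)
    return float(np.sum(intra / m - (deg / (2.0 * m)) ** 2))


def _component_partition(graph: Graph) -> Partition:
    return Partition.from_sets(connected_components(graph))


@dataclass
class EBCTrace:
    removed_edges: list[tuple[tuple[str, str], float]]
    best_partition: Partition
    best_modularity: float


def cluster_girvan_newman(
    graph: Graph,
    removal_fraction: float = 0.2,
    *,
    weighted: bool = True,
    weight_as_similarity: bool = False,
) -> EBCTrace:
    """Girvan-Newman sweep: repeatedly remove the highest-betweenness
    edge (recomputing betweenness each step), never removing an edge
    that would isolate a node, for a budget of
    ``ceil(removal_fraction * m)`` removals.  Returns the removal trace
    and the component partition of maximal modularity seen.
    """
    if not (0.0 <= removal_fraction <= 1.0):
        raise ValueError("removal_fraction must be in [0, 1]")
    if graph.m < 1:
        raise ValueError("need at least one edge")
    work = graph.copy()
    budget = math.ceil(removal_fraction * graph.m)
    best_part = _component_partition(work)
    best_q = modularity(graph, best_part)
    removed: list[tuple[tuple[str, str], float]] = []
    for _ in range(budget):
        eb = edge_betweenness(work, weighted=weighted, weight_as_similarity=weight_as_similarity)
        candidate = None
        for key, _val in sorted(eb.items(), key=lambda kv: (-kv[1], kv[0])):
            u, v = key
            if work.degree(u) > 1 and work.degree(v) > 1:  # singleton protection
                candidate = key
                break
        if candidate is None:
            break
        removed.append((candidate, eb[candidate]))
        work.remove_edge(*candidate)
        part = _component_partition(work)
        q = modularity(graph, part)
        if q > best_q:
            best_q, best_part = q, part
    return EBCTrace(removed_edges=removed, best_partition=best_part, best_modularity=best_q)


@dataclass
class MCLParams:
    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tol: float = 1e-6
    add_self_loops: bool = True  # standard regularization for convergence

    def __post_init__(self) -> None:
        if self.inflation <= 1.0:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


def cluster_mcl(graph: Graph, params: MCLParams | None = None) -> tuple[Partition, bool]:
    """Markov clustering: alternate expansion (matrix power, flow
    spreads along walks) and inflation (entrywise power + column
    renormalization, flow sharpens into basins) on the column-stochastic
    transition matrix until the matrix stops changing.

    Returns the partition and a convergence flag (False when the
    iteration hit ``max_iterations`` first).
    """
    params = params or MCLParams()
    order = sorted(graph.node_ids)
    n = len(order)
    if n == 0:
        return Partition({}), True
    index = {nid: i for i, nid in enumerate(order)}
    rows, cols, vals = [], [], []
    for e in graph.edges:
        i, j = index[e.source], index[e.target]
        rows += [i, j]
        cols += [j, i]
        vals += [e.weight, e.weight]
    if params.add_self_loops:
        rows += list(range(n))
        cols += list(range(n))
        vals += [1.0] * n
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    mat = _column_normalize(mat)
    converged = False
    for _ in range(params.max_iterations):
        prev = mat.copy()
        power = mat
        for _ in range(params.expansion - 1):
            power = power @ mat
        mat = power.power(params.inflation)
        mat = _column_normalize(mat)
        mat.data[mat.data < params.prune_threshold] = 0.0
        mat.eliminate_zeros()
        mat = _column_normalize(mat)
        diff = abs(mat - prev)
        if diff.nnz == 0 or diff.max() < params.convergence_tol:
            converged = True
            break
    # clusters: connected components of the non-zero flow structure
    structure = mat + mat.T
    n_comp, labels = sp.csgraph.connected_components(structure, directed=False)
    return Partition({order[i]: int(labels[i]) for i in range(n)}), converged


def _column_normalize(mat: sp.csr_matrix) -> sp.csr_matrix:
    sums = np.asarray(mat.sum(axis=0)).ravel()
    sums[sums == 0.0] = 1.0
    return (mat @ sp.diags(1.0 / sums)).tocsr()


def cluster_leading_eigenvector(graph: Graph) -> Partition:
    """Newman's leading-eigenvector method: recursively split groups by
    the sign of the leading eigenvector of the (weight-aware) modularity
    matrix; a split is accepted only if it increases Q.
    """
    if graph.m < 1:
        raise ValueError("need at least one edge")
    order = sorted(graph.node_ids)
    index = {nid: i for i, nid in enumerate(order)}
    n = len(order)
    adj = np.zeros((n, n))
    for e in graph.edges:
        i, j = index[e.source], index[e.target]
        adj[i, j] += e.weight
        adj[j, i] += e.weight
    deg = adj.sum(axis=1)
    two_m = deg.sum()
    mod_matrix = adj - np.outer(deg, deg) / two_m

    groups: list[list[int]] = []

    def split(members: list[int]) -> None:
        if len(members) < 2:
            groups.append(members)
            return
        sub = mod_matrix[np.ix_(members, members)]
        bg = sub - np.diag(sub.sum(axis=1))  # group-restricted modularity matrix
        eigvals, eigvecs = np.linalg.eigh(bg)
        lead = eigvecs[:, -1]
        if eigvals[-1] <= 1e-12:
            groups.append(members)
            return
        s = np.where(lead >= 0.0, 1.0, -1.0)
        delta_q = float(s @ bg @ s) / (2.0 * two_m)
        if delta_q <= 1e-10 or abs(s.sum()) == len(s):
            groups.append(members)
            return
        part_a = [m for m, si in zip(members, s) if si > 0]
        part_b = [m for m, si in zip(members, s) if si < 0]
        split(part_a)
        split(part_b)

    split(list(range(n)))
    membership: dict[str, int] = {}
    for lab, members in enumerate(sorted(groups, key=lambda g: min(g))):
        for i in members:
            membership[order[i]] = lab
    return Partition(membership)
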