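"""Network topology statistics: degree, neighborhood connectivity,
clustering coefficients, closeness, betweenness, shortest-path metrics,
shared nearest neighbors — per-node tables (rank-ordered), network-level
summaries, and distribution series.

Two conventions run through every metric here: edge weights are path
*lengths* for all shortest-path quantities, and only nodes whose
connected component has more than 3 nodes enter the clustering
coefficient and closeness statistics (smaller fragments report blank,
not zero).  For graphs beyond ``EXACT_LIMIT`` nodes, betweenness and
shortest-path load fall back to a fixed sample of source pivots so that
report generation stays tractable on large networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .graph_core import Graph, connected_components

__all__ = [
    "StatsReport",
    "EXACT_LIMIT",
    "degree_distribution",
    "neighborhood_connectivity",
    "clustering_coefficients",
    "closeness_centrality",
    "betweenness_centrality",
    "path_metrics",
    "shared_nearest_neighbors",
    "generate_report",
]

EXACT_LIMIT = 1500  # above this, betweenness/load use sampled pivots
_SAMPLE_PIVOTS = 200
_MIN_COMPONENT = 4  # ">3 nodes" exclusion rule, strictly greater


def _weight_attr(graph: Graph) -> str | None:
    return "weight" if any(e.weight != 1.0 for e in graph.edges) else None


def degree_distribution(graph: Graph) -> tuple[dict[int, int], dict[str, int]]:
    """(histogram degree -> count, per-node degrees)."""
    degrees = {nid: graph.degree(nid) for nid in graph.node_ids}
    hist: dict[int, int] = {}
    for d in degrees.values():
        hist[d] = hist.get(d, 0) + 1
    return hist, degrees


def neighborhood_connectivity(graph: Graph) -> tuple[dict[str, float | None], dict[int, float]]:
    """Mean neighbor degree per node (None for isolated nodes) and the
    series of that metric averaged over nodes of equal degree."""
    per_node: dict[str, float | None] = {}
    for nid in graph.node_ids:
        nbrs = graph.neighbors(nid)
        per_node[nid] = (sum(graph.degree(v) for v in nbrs) / len(nbrs)) if nbrs else None
    series: dict[int, float] = {}
    by_degree: dict[int, list[float]] = {}
    for nid, val in per_node.items():
        if val is not None:
            by_degree.setdefault(graph.degree(nid), []).append(val)
    for deg, vals in sorted(by_degree.items()):
        series[deg] = float(np.mean(vals))
    return per_node, series


def _eligible_nodes(graph: Graph) -> set[str]:
    out: set[str] = set()
    for comp in connected_components(graph):
        if len(comp) >= _MIN_COMPONENT:
            out |= comp
    return out


def clustering_coefficients(graph: Graph) -> tuple[dict[str, float], float | None]:
    """Local clustering coefficient per eligible node and the network
    average.  C_i = 2 e_i / (k_i (k_i - 1)) for k_i >= 2, else 0; nodes
    in components of <= 3 nodes are excluded entirely."""
    eligible = _eligible_nodes(graph)
    g = graph.to_networkx()
    values = nx.clustering(g, nodes=eligible or None) if eligible else {}
    per_node = {nid: float(values[nid]) for nid in eligible}
    avg = float(np.mean(list(per_node.values()))) if per_node else None
    return per_node, avg


def closeness_centrality(graph: Graph, *, normalized: bool = False) -> tuple[dict[str, float], float | None]:
    """Raw reciprocal-sum closeness within each node's own component
    (weights as lengths); components of <= 3 nodes are excluded.  The
    network value is the mean over evaluated nodes.  ``normalized``
    multiplies by (component size - 1) for cross-graph comparability."""
    import scipy.sparse as sp
    import scipy.sparse.csgraph as csgraph

    weight = _weight_attr(graph)
    per_node: dict[str, float] = {}
    for comp in connected_components(graph):
        if len(comp) < _MIN_COMPONENT:
            continue
        order = sorted(comp)
        index = {nid: i for i, nid in enumerate(order)}
        rows, cols, vals = [], [], []
        for e in graph.edges:
            if e.source in index and e.target in index:
                i, j = index[e.source], index[e.target]
                rows += [i, j]
                cols += [j, i]
                vals += [e.weight, e.weight]
        mat = sp.csr_matrix((vals, (rows, cols)), shape=(len(order), len(order)))
        dist = csgraph.dijkstra(mat, directed=False, unweighted=weight is None)
        totals = dist.sum(axis=1)  # self-distance is 0
        scale = (len(order) - 1) if normalized else 1.0
        for i, nid in enumerate(order):
            per_node[nid] = scale / totals[i] if totals[i] > 0 else 0.0
    avg = float(np.mean(list(per_node.values()))) if per_node else None
    return per_node, avg


def betweenness_centrality(graph: Graph, *, pivots: int | None = None, seed: int = 0) -> dict[str, float]:
    """Node betweenness (fractional credit across tied shortest paths,
    each unordered pair counted once).  ``pivots`` samples that many
    source nodes for large graphs; None means exact below EXACT_LIMIT."""
    g = graph.to_networkx()
    weight = _weight_attr(graph)
    k = pivots
    if k is None and graph.n > EXACT_LIMIT:
        k = _SAMPLE_PIVOTS
    if k is not None:
        k = min(k, graph.n)
    bc = nx.betweenness_centrality(g, k=k, normalized=False, weight=weight, seed=seed)
    return {nid: float(v) for nid, v in bc.items()}


def _stress_from_source(g: nx.Graph, source, weight: str | None) -> dict:
    """Brandes-style accumulation of shortest-path *counts* through each
    node (stress), from one source."""
    import heapq

    sigma = {v: 0.0 for v in g}
    sigma[source] = 1.0
    dist = {}
    preds = {v: [] for v in g}
    order = []
    if weight is None:
        from collections import deque

        dist[source] = 0
        queue = deque([source])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in g[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist.get(w) == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
    else:
        seen = {source: 0.0}
        heap = [(0.0, source, source)]
        while heap:
            d, pred, v = heapq.heappop(heap)
            if v in dist:
                continue
            dist[v] = d
            order.append(v)
            for w, data in g[v].items():
                nd = d + data.get(weight, 1.0)
                if w not in dist and (w not in seen or nd < seen[w] - 1e-12):
                    seen[w] = nd
                    heapq.heappush(heap, (nd, v, w))
                    sigma[w] = sigma[v]
                    preds[w] = [v]
                elif w not in dist and abs(nd - seen.get(w, math.inf)) <= 1e-12:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
    # paths through v as an interior vertex = sigma[v] * onward[v],
    # where onward[v] counts shortest paths from v to targets beyond it
    npaths = {v: 0.0 for v in g}
    onward = {v: 0.0 for v in g}
    for v in reversed(order):
        for p in preds[v]:
            onward[p] += 1.0 + onward[v]
    for v in order:
        if v != source:
            npaths[v] = sigma[v] * onward[v]
    return npaths


def path_metrics(graph: Graph, *, pivots: int | None = None, seed: int = 0):
    """(diameter, average shortest-path length, per-node shortest-path load).

    Distances use weights as lengths; unconnected pairs are ignored
    (diameter is the largest finite distance).  Load counts the number
    of shortest paths passing through each node as an interior vertex.
    Edgeless graphs report diameter None.
    """
    g = graph.to_networkx()
    weight = _weight_attr(graph)
    nodes = list(g)
    load = {nid: 0.0 for nid in nodes}
    if graph.m == 0:
        return None, None, load
    k = pivots
    if k is None and graph.n > EXACT_LIMIT:
        k = _SAMPLE_PIVOTS
    if k is not None and k < len(nodes):
        rng = np.random.default_rng(seed)
        sources = list(rng.choice(nodes, size=k, replace=False))
        scale = len(nodes) / k
    else:
        sources = nodes
        scale = 1.0
    diameter = 0.0
    total = 0.0
    pairs = 0
    for s in sources:
        dists = (
            nx.single_source_dijkstra_path_length(g, s, weight=weight)
            if weight
            else {v: float(d) for v, d in nx.single_source_shortest_path_length(g, s).items()}
        )
        finite = [d for v, d in dists.items() if v != s]
        if finite:
            diameter = max(diameter, max(finite))
            total += sum(finite)
            pairs += len(finite)
        stress = _stress_from_source(g, s, weight)
        for v, val in stress.items():
            if v != s:
                load[v] += val
    avg = total / pairs if pairs else None
    # every unordered pair visited twice when sweeping all sources
    if scale == 1.0:
        load = {v: val / 2.0 for v, val in load.items()}
    else:
        load = {v: val * scale / 2.0 for v, val in load.items()}
    return diameter, avg, load


def shared_nearest_neighbors(graph: Graph) -> dict[tuple[str, str], int]:
    """SNN(u, v) = |N(u) ∩ N(v)| for pairs with at least one shared
    direct neighbor (sparse: other pairs are omitted)."""
    counts: dict[tuple[str, str], int] = {}
    for nid in graph.node_ids:
        nbrs = sorted(graph.neighbors(nid))
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                key = (nbrs[i], nbrs[j])
                counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass
class StatsReport:
    per_node: pd.DataFrame  # rank-ordered rows
    network: dict[str, float | int | None]
    degree_histogram: dict[int, int]
    connectivity_series: dict[int, float]
    snn: dict[tuple[str, str], int]
    rank_by: str = "degree"


_METRICS = (
    "degree",
    "neighborhood_connectivity",
    "clustering_coefficient",
    "closeness",
    "betweenness",
    "shortest_path_load",
    "snn_max",
)


def generate_report(
    graph: Graph,
    rank_by: str = "degree",
    out_dir: str | Path | None = None,
    *,
    seed: int = 0,
) -> StatsReport:
    """Full topology report: per-node metric table rank-ordered by
    ``rank_by``, network summary, distribution series; optionally writes
    CSV tables and PNG distribution plots to ``out_dir``."""
    if rank_by not in _METRICS:
        raise ValueError(f"unknown metric {rank_by!r}; valid: {', '.join(_METRICS)}")
    hist, degrees = degree_distribution(graph)
    conn, series = neighborhood_connectivity(graph)
    cc, cc_avg = clustering_coefficients(graph)
    close, close_avg = closeness_centrality(graph)
    bet = betweenness_centrality(graph, seed=seed)
    diameter, avg_path, load = path_metrics(graph, seed=seed)
    snn = shared_nearest_neighbors(graph)
    snn_max: dict[str, int] = {nid: 0 for nid in graph.node_ids}
    for (u, v), c in snn.items():
        snn_max[u] = max(snn_max[u], c)
        snn_max[v] = max(snn_max[v], c)
    rows = []
    for nid in sorted(graph.node_ids):
        rows.append(
            {
                "id": nid,
                "degree": degrees[nid],
                "neighborhood_connectivity": conn[nid],
                "clustering_coefficient": cc.get(nid),  # blank outside >3-node components
                "closeness": close.get(nid),
                "betweenness": bet[nid],
                "shortest_path_load": load[nid],
                "snn_max": snn_max[nid],
            }
        )
    table = pd.DataFrame(rows, columns=["id", *_METRICS])
    if len(table):
        table = table.sort_values([rank_by, "id"], ascending=[False, True], na_position="last")
        table = table.reset_index(drop=True)
    network = {
        "n": graph.n,
        "m": graph.m,
        "diameter": diameter,
        "average_clustering_coefficient": cc_avg,
        "network_closeness": close_avg,
        "average_shortest_path_length": avg_path,
    }
    report = StatsReport(
        per_node=table,
        network=network,
        degree_histogram=hist,
        connectivity_series=series,
        snn=snn,
        rank_by=rank_by,
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: StatsReport, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    report.per_node.to_csv(out_dir / "per_node.csv", index=False)
    pd.DataFrame(
        [{"metric": k, "value": v} for k, v in report.network.items()]
    ).to_csv(out_dir / "network.csv", index=False)
    pd.DataFrame(
        [{"u": u, "v": v, "snn": c} for (u, v), c in sorted(report.snn.items())]
    ).to_csv(out_dir / "snn.csv", index=False)

    fig, ax = plt.subplots(figsize=(6, 4), dpi=150)
    if report.degree_histogram:
        degs = sorted(report.degree_histogram)
        ax.bar(degs, [report.degree_histogram[d] for d in degs], color="#4878a8")
    ax.set_xlabel("degree")
    ax.set_ylabel("node count")
    ax.set_facecolor("white")
    fig.patch.set_facecolor("white")
    fig.tight_layout()
    fig.savefig(out_dir / "degree_distribution.png", facecolor="white")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4), dpi=150)
    if report.connectivity_series:
        degs = sorted(report.connectivity_series)
        ax.plot(degs, [report.connectivity_series[d] for d in degs], "o-", color="#a84848")
    ax.set_xlabel("degree")
    ax.set_ylabel("mean neighborhood connectivity")
    fig.patch.set_facecolor("white")
    fig.tight_layout()
    fig.savefig(out_dir / "neighborhood_connectivity.png", facecolor="white")
    plt.close(fig)
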