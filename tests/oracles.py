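"""Independent brute-force oracles for shortest-path quantities.

These enumerate every simple path between every node pair by plain DFS
on the adjacency dictionary — no shortest-path library code — so they
stay independent of the implementations they check.  Usable only at toy
sizes (n <= ~10).
"""

from __future__ import annotations

import math
from itertools import combinations

TOL = 1e-12


def enumerate_shortest_paths(graph):
    """{(u, v): (distance, [paths])} for unordered pairs, u < v; pairs
    with no connecting path are omitted.  Edge weights are lengths."""
    ids = sorted(graph.node_ids)
    adj = {nid: {v: graph.edge(nid, v).weight for v in graph.neighbors(nid)} for nid in ids}
    result = {}
    for u, v in combinations(ids, 2):
        best = math.inf
        paths: list[list[str]] = []

        def dfs(node, dist, path):
            nonlocal best, paths
            if dist > best + TOL:
                return
            if node == v:
                if dist < best - TOL:
                    best, paths = dist, [list(path)]
                else:
                    paths.append(list(path))
                return
            for w in sorted(adj[node]):
                if w not in path:
                    path.append(w)
                    dfs(w, dist + adj[node][w], path)
                    path.pop()

        dfs(u, 0.0, [u])
        if paths:
            result[(u, v)] = (best, paths)
    return result


def oracle_edge_betweenness(graph):
    eb = {e.key: 0.0 for e in graph.edges}
    for (_u, _v), (_d, paths) in enumerate_shortest_paths(graph).items():
        share = 1.0 / len(paths)
        for path in paths:
            for a, b in zip(path, path[1:]):
                eb[(min(a, b), max(a, b))] += share
    return eb


def oracle_betweenness(graph):
    bc = {nid: 0.0 for nid in graph.node_ids}
    for (_u, _v), (_d, paths) in enumerate_shortest_paths(graph).items():
        share = 1.0 / len(paths)
        for path in paths:
            for interior in path[1:-1]:
                bc[interior] += share
    return bc


def oracle_stress_load(graph):
    load = {nid: 0.0 for nid in graph.node_ids}
    for (_u, _v), (_d, paths) in enumerate_shortest_paths(graph).items():
        for path in paths:
            for interior in path[1:-1]:
                load[interior] += 1.0
    return load


def oracle_closeness(graph, min_component: int = 4):
    """Raw reciprocal-sum closeness with the >3-node component rule."""
    sp = enumerate_shortest_paths(graph)
    # component discovery by reachability in the oracle's own terms
    comp_of = {}
    for nid in graph.node_ids:
        comp_of.setdefault(nid, {nid})
    for (u, v) in sp:
        merged = comp_of[u] | comp_of[v]
        for nid in merged:
            comp_of[nid] = merged
    totals = {nid: 0.0 for nid in graph.node_ids}
    for (u, v), (d, _paths) in sp.items():
        totals[u] += d
        totals[v] += d
    out = {}
    for nid in graph.node_ids:
        if len(comp_of[nid]) >= min_component and totals[nid] > 0:
            out[nid] = 1.0 / totals[nid]
    return out


def oracle_diameter(graph):
    sp = enumerate_shortest_paths(graph)
    return max((d for d, _ in sp.values()), default=None)
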