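"""Cluster-level layouts: transparent bubbles with hemispherical
interiors (cluster centers from force-directed or lin-log layout of the
quotient graph) and the 3D Circos sliced-hemisphere layout."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph_core import Edge, Graph, Layout3D, Partition
from .layouts import (
    GOLDEN_ANGLE,
    FRParams,
    HemisphereSpec,
    LinLogParams,
    hemisphere_position,
    layout_force_directed,
    layout_linlog,
    sphere_point,
)

__all__ = ["BubbleLayout", "quotient_graph", "layout_cluster_bubbles", "layout_circos3d"]


@dataclass
class BubbleLayout:
    centers: dict[int, np.ndarray]
    radii: dict[int, float]
    node_positions: Layout3D
    slice_bounds: dict[int, tuple[float, float]] | None = None  # Circos: (lon_start, lon_end) deg


def quotient_graph(graph: Graph, partition: Partition, *, sum_weights: bool = False) -> Graph:
    """One node per cluster; edge weight = count (or weight sum) of
    inter-cluster edges; no self-edges."""
    q = Graph()
    for lab in range(partition.k):
        q.add_node(str(lab))
    for e in graph.edges:
        cu = partition.membership[e.source]
        cv = partition.membership[e.target]
        if cu != cv:
            w = e.weight if sum_weights else 1.0
            q.add_edge(Edge(str(cu), str(cv), w))
    return q


def _cluster_sizes(partition: Partition) -> dict[int, int]:
    sizes: dict[int, int] = {lab: 0 for lab in range(partition.k)}
    for lab in partition.membership.values():
        sizes[lab] += 1
    return sizes


def layout_cluster_bubbles(
    graph: Graph,
    partition: Partition,
    mode: str = "fd",
    *,
    seed: int = 0,
    sum_weights: bool = False,
) -> BubbleLayout:
    """Position each cluster as a bubble, members on its hemisphere.

    Bubble centers come from a force-directed (``mode="fd"``) or
    lin-log (``mode="linlog"``) layout of the quotient graph, so highly
    interconnected clusters sit closer together.  Bubble radius scales
    with the cube root of cluster size; a final rescale pass grows
    center separations until no two bubbles overlap.
    """
    if mode not in ("fd", "linlog"):
        raise ValueError(f"unknown mode {mode!r}; expected 'fd' or 'linlog'")
    k = partition.k
    if k < 1:
        raise ValueError("need at least one cluster")
    q = quotient_graph(graph, partition, sum_weights=sum_weights)
    if k == 1:
        centers = {0: np.zeros(3)}
    elif mode == "fd":
        lay = layout_force_directed(q, FRParams(volume=1000.0, seed=seed))
        centers = {int(nid): lay.positions[nid] for nid in q.node_ids}
    else:
        lay = layout_linlog(q, LinLogParams(r=1.0, seed=seed))
        centers = {int(nid): lay.positions[nid] for nid in q.node_ids}
    sizes = _cluster_sizes(partition)
    span = 1.0
    if k > 1:
        pts = np.array([centers[lab] for lab in sorted(centers)])
        span = max(float(np.max(np.ptp(pts, axis=0))), 1e-9)
    c = 0.15 * span / max(s ** (1.0 / 3.0) for s in sizes.values())
    radii = {lab: c * sizes[lab] ** (1.0 / 3.0) for lab in sorted(sizes)}
    centers = _separate_bubbles(centers, radii)
    positions: dict[str, np.ndarray] = {}
    clusters = partition.clusters()
    for lab in sorted(centers):
        members = sorted(clusters[lab])
        sub = graph.subgraph(members)
        spec = HemisphereSpec(R=radii[lab], center=tuple(centers[lab]))
        ranked = sorted(members, key=lambda nid: (-sub.degree(nid), nid))
        for i, nid in enumerate(ranked):
            positions[nid] = hemisphere_position(i, len(ranked), spec)
    return BubbleLayout(centers=centers, radii=radii, node_positions=Layout3D(positions, volume=1000.0))


def _separate_bubbles(centers: dict[int, np.ndarray], radii: dict[int, float]) -> dict[int, np.ndarray]:
    """Uniformly scale center offsets about the centroid until no two
    bubbles overlap (margin 5% of the larger radius)."""
    labs = sorted(centers)
    if len(labs) < 2:
        return {lab: np.asarray(c, dtype=float) for lab, c in centers.items()}
    pts = np.array([centers[lab] for lab in labs], dtype=float)
    centroid = pts.mean(axis=0)
    # coincident centers (e.g. edgeless quotient collapsing) get a deterministic spread
    for i, lab in enumerate(labs):
        if np.linalg.norm(pts[i] - centroid) < 1e-12:
            ang = 2.0 * math.pi * i / len(labs)
            pts[i] += max(radii[lab], 1e-3) * np.array([math.cos(ang), math.sin(ang), 0.0])
    for _ in range(200):
        worst = 0.0
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                need = (radii[labs[i]] + radii[labs[j]]) * 1.05
                d = float(np.linalg.norm(pts[i] - pts[j]))
                if d < need:
                    worst = max(worst, need / max(d, 1e-12))
        if worst <= 1.0:
            break
        pts = centroid + (pts - centroid) * worst
    return {lab: pts[i] for i, lab in enumerate(labs)}


def layout_circos3d(
    graph: Graph, partition: Partition, spec: HemisphereSpec | None = None
) -> BubbleLayout:
    """Sliced-hemisphere (3D Circos) layout.

    The longitude circle [0, 360) is cut into one contiguous slice per
    cluster with angular width proportional to cluster size.  The
    cluster holding the globally most connected node takes the first
    slice; remaining slices follow in decreasing cluster size (ties by
    label).  Within a slice, nodes descend pole-to-rim in decreasing
    degree order along the slice's own spiral, so each slice's hub sits
    nearest the pole.
    """
    spec = spec or HemisphereSpec()
    k = partition.k
    if k < 1:
        raise ValueError("need at least one cluster")
    sizes = _cluster_sizes(partition)
    n = graph.n
    top_node = max(graph.node_ids, key=lambda nid: (graph.degree(nid), nid)) if n else None
    first = partition.membership[top_node] if top_node is not None else 0
    rest = sorted((lab for lab in sizes if lab != first), key=lambda lab: (-sizes[lab], lab))
    order = [first] + rest
    bounds: dict[int, tuple[float, float]] = {}
    lon = 0.0
    for lab in order:
        width = 360.0 * sizes[lab] / max(n, 1)
        bounds[lab] = (lon, lon + width)
        lon += width
    clusters = partition.clusters()
    positions: dict[str, np.ndarray] = {}
    for lab in order:
        members = sorted(clusters[lab])
        sub = graph.subgraph(members)
        ranked = sorted(members, key=lambda nid: (-sub.degree(nid), nid))
        lon_start, lon_end = bounds[lab]
        width = lon_end - lon_start
        s = len(ranked)
        for i, nid in enumerate(ranked):
            sin_lat = 1.0 - (i + 0.5) / s
            lat = math.degrees(math.asin(sin_lat))
            frac = (i * GOLDEN_ANGLE / (2.0 * math.pi)) % 1.0
            node_lon = lon_start + width * (0.05 + 0.9 * frac)  # keep inside the panel
            positions[nid] = sphere_point(lat, node_lon, spec.R, spec.center)
    node_layout = Layout3D(positions, volume=(2.0 * spec.R) ** 3)
    node_layout.hemisphere = (np.array(spec.center, dtype=float), spec.R)
    center = np.array(spec.center, dtype=float)
    return BubbleLayout(
        centers={lab: center for lab in order},
        radii={lab: spec.R for lab in order},
        node_positions=node_layout,
        slice_bounds=bounds,
    )
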