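"""3D force-directed edge bundling.

Edges are subdivided into polylines whose interior points feel two
forces: a spring force between neighboring points of the same edge, and
an electrostatic attraction between corresponding points of *compatible*
edge pairs.  Compatibility is the product of four factors — angle,
scale (length), position, and visibility — each in [0, 1]; pairs above
a threshold bundle together, which visually merges adjacent edges into
wire-like highways.  Endpoints never move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph_core import Graph, Layout3D

__all__ = ["BundleParams", "BundledEdge", "edge_compatibility", "bundle_edges"]


@dataclass
class BundleParams:
    compat_threshold: float = 0.6
    cycles: int = 6
    initial_subdivisions: int = 1
    step_size: float | None = None  # default 0.04 * mean edge length
    spring_constant: float = 0.1
    iterations_per_cycle: int = 50
    directional: bool = False  # flip antiparallel partners instead of |cos|
    max_partners: int | None = None  # None = adaptive (20 for m > 2000)

    def __post_init__(self) -> None:
        if not (0.0 <= self.compat_threshold <= 1.1):
            raise ValueError("compat_threshold must be in [0, 1] (or >1 to disable bundling)")
        if self.cycles < 1 or self.initial_subdivisions < 1:
            raise ValueError("cycles and initial_subdivisions must be >= 1")


@dataclass
class BundledEdge:
    edge: tuple[str, str]
    points: np.ndarray  # (n_points, 3); first/last are the node positions

    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


def _segment_compat(p0, p1, q0, q1) -> float:
    P = p1 - p0
    Q = q1 - q0
    lp = float(np.linalg.norm(P))
    lq = float(np.linalg.norm(Q))
    if lp == 0.0 or lq == 0.0:
        raise ValueError("zero-length segment has no direction; filter degenerate edges")
    cos_theta = float(np.dot(P, Q)) / (lp * lq)
    c_angle = abs(cos_theta)
    l_avg = (lp + lq) / 2.0
    c_scale = 2.0 / (l_avg / min(lp, lq) + max(lp, lq) / l_avg)
    pm = (p0 + p1) / 2.0
    qm = (q0 + q1) / 2.0
    c_pos = l_avg / (l_avg + float(np.linalg.norm(pm - qm)))

    def visibility(a0, a1, b0, b1) -> float:
        dir_a = a1 - a0
        denom = float(np.dot(dir_a, dir_a))
        t0 = float(np.dot(b0 - a0, dir_a)) / denom
        t1 = float(np.dot(b1 - a0, dir_a)) / denom
        i0 = a0 + t0 * dir_a
        i1 = a0 + t1 * dir_a
        im = (i0 + i1) / 2.0
        am = (a0 + a1) / 2.0
        denom_len = float(np.linalg.norm(i0 - i1))
        if denom_len == 0.0:
            return 0.0
        return max(0.0, 1.0 - 2.0 * float(np.linalg.norm(am - im)) / denom_len)

    c_vis = min(visibility(p0, p1, q0, q1), visibility(q0, q1, p0, p1))
    return c_angle * c_scale * c_pos * c_vis


def edge_compatibility(p: tuple[np.ndarray, np.ndarray], q: tuple[np.ndarray, np.ndarray]) -> float:
    """Total compatibility of two straight edge segments: the product of
    angle, scale, position and visibility factors, each in [0, 1].
    Symmetric; 1 exactly for identical (or direction-reversed) segments,
    0 for perpendicular ones."""
    return _segment_compat(np.asarray(p[0], float), np.asarray(p[1], float), np.asarray(q[0], float), np.asarray(q[1], float))


def _compat_matrix(starts: np.ndarray, ends: np.ndarray, threshold: float, max_partners: int | None):
    """Pairs (i, j, compat, flip) with compat >= threshold, fully
    vectorized in row blocks.

    The visibility factor collapses to a function of the two projection
    parameters t0, t1 of the partner's endpoints onto an edge's line:
    vis = max(0, 1 - |1 - t0 - t1| / |t1 - t0|).
    """
    m = starts.shape[0]
    vec = ends - starts
    lens = np.linalg.norm(vec, axis=1)
    len2 = lens * lens
    mids = (starts + ends) / 2.0
    # per-edge dot products reused across blocks
    s_dot_v = np.einsum("ij,ij->i", starts, vec)  # p0 . v
    e_dot_v = np.einsum("ij,ij->i", ends, vec)  # p1 . v
    pairs: list[tuple[int, int, float, bool]] = []
    block = max(1, 2_000_000 // max(m, 1))
    for lo in range(0, m, block):
        hi = min(lo + block, m)
        cos = (vec[lo:hi] @ vec.T) / np.outer(lens[lo:hi], lens)
        c_angle = np.abs(cos)
        l_avg = (lens[lo:hi, None] + lens[None, :]) / 2.0
        mn = np.minimum(lens[lo:hi, None], lens[None, :])
        mx = np.maximum(lens[lo:hi, None], lens[None, :])
        c_scale = 2.0 / (l_avg / mn + mx / l_avg)
        mid_d = np.linalg.norm(mids[lo:hi, None, :] - mids[None, :, :], axis=2)
        c_pos = l_avg / (l_avg + mid_d)
        # visibility of Q_j seen from P_i's line
        q0_dot_vi = starts @ vec[lo:hi].T  # (m, B) -> use transposed below
        q1_dot_vi = ends @ vec[lo:hi].T
        t0 = (q0_dot_vi.T - s_dot_v[lo:hi, None]) / len2[lo:hi, None]
        t1 = (q1_dot_vi.T - s_dot_v[lo:hi, None]) / len2[lo:hi, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            vis_pq = np.maximum(0.0, 1.0 - np.abs(1.0 - t0 - t1) / np.abs(t1 - t0))
        vis_pq = np.nan_to_num(vis_pq)
        # visibility of P_i seen from Q_j's line
        p0_dot_vj = starts[lo:hi] @ vec.T  # (B, m)
        p1_dot_vj = ends[lo:hi] @ vec.T
        s0 = (p0_dot_vj - s_dot_v[None, :]) / len2[None, :]
        s1 = (p1_dot_vj - s_dot_v[None, :]) / len2[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            vis_qp = np.maximum(0.0, 1.0 - np.abs(1.0 - s0 - s1) / np.abs(s1 - s0))
        vis_qp = np.nan_to_num(vis_qp)
        compat = c_angle * c_scale * c_pos * np.minimum(vis_pq, vis_qp)
        ii, jj = np.nonzero(compat >= threshold)
        for bi, j in zip(ii, jj):
            i = lo + bi
            if j > i:
                pairs.append((i, int(j), float(compat[bi, j]), bool(cos[bi, j] < 0.0)))
    if max_partners is not None:
        counts: dict[int, list[tuple[float, int]]] = {}
        for idx, (i, j, c, _f) in enumerate(pairs):
            counts.setdefault(i, []).append((c, idx))
            counts.setdefault(j, []).append((c, idx))
        keep = set()
        for partner_list in counts.values():
            for _c, idx in sorted(partner_list, reverse=True)[:max_partners]:
                keep.add(idx)
        pairs = [pairs[idx] for idx in sorted(keep)]
    return pairs


def _resample(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to n_points by arc length (endpoints kept)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0.0:
        return np.repeat(points[:1], n_points, axis=0)
    targets = np.linspace(0.0, total, n_points)
    out = np.empty((n_points, 3))
    for c in range(3):
        out[:, c] = np.interp(targets, cum, points[:, c])
    out[0], out[-1] = points[0], points[-1]
    return out


def bundle_edges(layout: Layout3D, graph: Graph, params: BundleParams | None = None) -> list[BundledEdge]:
    """Bundle the graph's edges over the given layout.

    Deterministic (no randomness).  Per cycle the subdivision count
    doubles, the step size halves, and the iteration count halves, as in
    the published force-directed bundling scheme.  If the layout carries
    a hemisphere constraint, points are re-projected to the sphere
    surface after each cycle so bundles stay on the hemisphere.
    """
    params = params or BundleParams()
    edges = [e for e in graph.edges]
    keys = [e.key for e in edges]
    starts = np.array([layout.positions[k[0]] for k in keys], dtype=float).reshape(-1, 3)
    ends = np.array([layout.positions[k[1]] for k in keys], dtype=float).reshape(-1, 3)
    m = len(edges)
    if m == 0:
        return []
    lens = np.linalg.norm(ends - starts, axis=1)
    # zero-length edges (coincident endpoints) have no direction: they are
    # left as straight degenerate polylines and take no part in bundling
    valid = np.nonzero(lens > 0.0)[0]
    max_partners = params.max_partners
    if max_partners is None and m > 2000:
        max_partners = 20
    pairs = [
        (int(valid[i]), int(valid[j]), c, f)
        for i, j, c, f in _compat_matrix(
            starts[valid], ends[valid], params.compat_threshold, max_partners
        )
    ]
    lens = np.maximum(lens, 1e-12)
    step0 = params.step_size if params.step_size is not None else 0.04 * float(np.mean(lens))
    # polylines start straight with `initial_subdivisions` interior points
    n_interior = params.initial_subdivisions
    polylines = [
        np.linspace(starts[i], ends[i], n_interior + 2) for i in range(m)
    ]
    iters = params.iterations_per_cycle
    step = step0
    if pairs:
        i_arr = np.array([p[0] for p in pairs], dtype=int)
        j_arr = np.array([p[1] for p in pairs], dtype=int)
        c_arr = np.array([p[2] for p in pairs], dtype=float)
        flip_arr = np.array([p[3] and not params.directional for p in pairs], dtype=bool)
    for _cycle in range(params.cycles):
        P = np.stack(polylines)  # (m, pts, 3)
        n_pts = P.shape[1]
        kp = params.spring_constant / (lens * max(n_pts - 1, 1))  # spring stiffness per edge
        for _ in range(max(1, iters)):
            force = np.zeros_like(P)
            # spring force between neighboring points of the same edge
            force[:, 1:-1] += (P[:, :-2] + P[:, 2:] - 2.0 * P[:, 1:-1]) * kp[:, None, None]
            # electrostatic attraction between corresponding points of
            # compatible pairs (antiparallel partners pair up reversed)
            if pairs:
                block = max(1, 40_000_000 // max((n_pts - 2) * 3, 1))
                for lo in range(0, len(i_arr), block):
                    ib, jb = i_arr[lo : lo + block], j_arr[lo : lo + block]
                    cb, fb = c_arr[lo : lo + block], flip_arr[lo : lo + block]
                    other = P[jb][:, 1:-1]
                    if fb.any():
                        other[fb] = P[jb[fb]][:, ::-1][:, 1:-1]
                    diff = other - P[ib][:, 1:-1]
                    dist = np.maximum(np.linalg.norm(diff, axis=2), 1e-12)
                    f = cb[:, None, None] * diff / dist[:, :, None]
                    np.add.at(force[:, 1:-1], ib, f)
                    back = np.where(fb[:, None, None], -f[:, ::-1], -f)
                    np.add.at(force[:, 1:-1], jb, back)
            P[:, 1:-1] += step * force[:, 1:-1]
            if layout.hemisphere is not None:
                center, radius = layout.hemisphere
                rel = P[:, 1:-1] - center
                norms = np.maximum(np.linalg.norm(rel, axis=2, keepdims=True), 1e-12)
                P[:, 1:-1] = center + rel / norms * radius
        n_interior = n_interior * 2
        polylines = [_resample(P[i], n_interior + 2) for i in range(m)]
        for i in range(m):
            polylines[i][0] = starts[i]
            polylines[i][-1] = ends[i]
            if layout.hemisphere is not None:
                center, radius = layout.hemisphere
                rel = polylines[i][1:-1] - center
                norms = np.maximum(np.linalg.norm(rel, axis=1, keepdims=True), 1e-12)
                polylines[i][1:-1] = center + rel / norms * radius
        step /= 2.0
        iters = max(1, iters // 2)
    return [BundledEdge(edge=keys[i], points=polylines[i]) for i in range(m)]
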