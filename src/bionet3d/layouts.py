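"""Seven 3D network-layout engines.

Force-directed family (classic spring-embedder forces, lin-log energy
models, spectral-bisection hybrid, multilevel coarsening, simulated
annealing with edge cutting) plus two deterministic layouts that exploit
the third dimension directly: semantic z-levels and the hemispherical
degree-ranked layout.

All engines return a :class:`~bionet3d.graph_core.Layout3D`; every
stochastic engine is reproducible from its seed.  Iteration budgets are
size-adaptive: ``min(1000, max(50, 30*ceil(1e4/n)))`` — small graphs get
many refinement steps, large graphs fewer, so run time stays roughly
flat as networks grow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph_core import Graph, Layout3D

__all__ = [
    "FRParams",
    "LinLogParams",
    "CoarsenParams",
    "AnnealPhase",
    "AnnealSchedule",
    "SemanticParams",
    "HemisphereSpec",
    "BisectionResult",
    "fr_forces",
    "adaptive_iterations",
    "layout_force_directed",
    "linlog_energy",
    "layout_linlog",
    "spectral_bisect",
    "layout_hybrid",
    "coarsen",
    "layout_coarsened",
    "layout_annealed",
    "assign_semantic_layers",
    "layout_semantic",
    "sphere_point",
    "hemisphere_position",
    "layout_hemispherical",
]

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


def adaptive_iterations(n: int) -> int:
    """Size-adaptive iteration budget, non-increasing in ``n``."""
    if n <= 0:
        return 0
    return min(1000, max(50, 30 * math.ceil(1e4 / n)))


@dataclass
class FRParams:
    """Spring-embedder parameters.

    ``volume`` is the cubic layout space; the equilibrium edge length is
    ``k = (volume / n)^(1/3)``.  ``initial_step`` defaults to one tenth
    of the cube side; the temperature decays linearly to zero over the
    budget (``cooling`` selects an optional geometric decay instead).
    """

    volume: float = 1000.0
    iterations: int | None = None
    initial_step: float | None = None
    cooling: float | None = None  # None = linear decay; else multiplicative
    seed: int = 0

    def k(self, n: int) -> float:
        return (self.volume / max(n, 1)) ** (1.0 / 3.0)

    def side(self) -> float:
        return self.volume ** (1.0 / 3.0)

    def budget(self, n: int) -> int:
        return self.iterations if self.iterations is not None else adaptive_iterations(n)

    def temperatures(self, n: int) -> np.ndarray:
        t0 = self.initial_step if self.initial_step is not None else self.side() / 10.0
        budget = self.budget(n)
        if budget == 0:
            return np.zeros(0)
        if self.cooling is None:
            return t0 * (1.0 - np.arange(budget) / budget)
        return t0 * self.cooling ** np.arange(budget)


def fr_forces(d: float, k: float) -> tuple[float, float]:
    """Attractive and repulsive force magnitudes at distance ``d``.

    f_a = d^2/k pulls edge endpoints together, f_r = -k^2/d pushes every
    node pair apart; they balance at the equilibrium length d = k.
    """
    if d <= 0:
        raise ValueError("distance must be > 0 (jitter coincident nodes first)")
    if k <= 0:
        raise ValueError("equilibrium length k must be > 0")
    return d * d / k, -k * k / d


# ----------------------------------------------------------------------
# Shared spring-embedder core

def _pair_chunks(n: int, max_cells: int = 2_000_000):
    rows = max(1, max_cells // max(n, 1))
    for start in range(0, n, rows):
        yield start, min(start + rows, n)


def _net_forces(
    pos: np.ndarray,
    edges_idx: np.ndarray,
    k: float,
    *,
    cut_mask: np.ndarray | None = None,
    attraction_scale: float = 1.0,
) -> np.ndarray:
    """Net FR force vector per node (repulsion all pairs, attraction on edges)."""
    n = pos.shape[0]
    disp = np.zeros_like(pos)
    eps = 1e-4 * k
    for lo, hi in _pair_chunks(n):
        diff = pos[lo:hi, None, :] - pos[None, :, :]  # (rows, n, 3)
        dist = np.linalg.norm(diff, axis=2)
        np.maximum(dist, eps, out=dist)
        block = np.arange(lo, hi)
        dist[block - lo, block] = np.inf  # no self-repulsion
        disp[lo:hi] += np.einsum("ijc,ij->ic", diff, k * k / dist**2)
    if edges_idx.size:
        u, v = edges_idx[:, 0], edges_idx[:, 1]
        diff = pos[u] - pos[v]
        dist = np.maximum(np.linalg.norm(diff, axis=1), eps)
        mag = attraction_scale * dist / k  # |f_a|/d = d/k
        if cut_mask is not None:
            mag = np.where(cut_mask, 0.0, mag)
        pull = diff * mag[:, None]
        np.add.at(disp, u, -pull)
        np.add.at(disp, v, pull)
    return disp


def _fr_run(
    graph: Graph,
    order: list[str],
    pos: np.ndarray,
    temps: np.ndarray,
    k: float,
    side: float,
    rng: np.random.Generator,
    *,
    dim: int = 3,
    edge_cut: float = 0.0,
    attraction: np.ndarray | None = None,
) -> np.ndarray:
    """Iterate FR forces; returns the lowest-stress configuration seen.

    ``edge_cut`` in [0, 1] suppresses attraction on the longest
    ``ceil(edge_cut * m * progress)`` edges each iteration (0 = plain
    FR).  ``attraction`` optionally scales the attractive term per
    iteration.  Only the first ``dim`` coordinates move.
    """
    n = pos.shape[0]
    if n == 0 or temps.size == 0:
        return pos
    index = {nid: i for i, nid in enumerate(order)}
    edges_idx = np.array(
        [[index[e.source], index[e.target]] for e in graph.edges if e.source in index and e.target in index],
        dtype=int,
    ).reshape(-1, 2)
    m = edges_idx.shape[0]
    # separate exactly coincident nodes once, with the run's generator
    for _ in range(3):
        dup = _coincident_rows(pos)
        if not dup.size:
            break
        pos[dup] += 1e-4 * k * rng.standard_normal((dup.size, 3))
        if dim < 3:
            pos[dup, dim:] = 0.0
    budget = temps.size
    best = pos.copy()
    best_stress = np.inf
    half = side / 2.0
    for t, temp in enumerate(temps):
        cut_mask = None
        if edge_cut > 0.0 and m:
            progress = (t + 1) / budget
            n_cut = min(m - 0, math.ceil(edge_cut * m * progress))
            if n_cut > 0:
                lengths = np.linalg.norm(pos[edges_idx[:, 0]] - pos[edges_idx[:, 1]], axis=1)
                cut_mask = np.zeros(m, dtype=bool)
                cut_mask[np.argsort(-lengths, kind="stable")[:n_cut]] = True
        scale = 1.0 if attraction is None else float(attraction[t])
        net = _net_forces(pos, edges_idx, k, cut_mask=cut_mask, attraction_scale=scale)
        if dim < 3:
            net[:, dim:] = 0.0
        stress = float(np.sum(np.linalg.norm(net, axis=1)))
        if stress < best_stress:
            best_stress = stress
            best = pos.copy()
        mag = np.linalg.norm(net, axis=1)
        nz = mag > 0
        step = np.zeros_like(pos)
        step[nz] = net[nz] / mag[nz, None] * np.minimum(mag[nz], temp)[:, None]
        pos = np.clip(pos + step, -half, half)
    net = _net_forces(pos, edges_idx, k)
    if dim < 3:
        net[:, dim:] = 0.0
    if float(np.sum(np.linalg.norm(net, axis=1))) < best_stress:
        best = pos
    return best


def _coincident_rows(pos: np.ndarray) -> np.ndarray:
    """Indices of rows that duplicate an earlier row exactly."""
    seen: dict[bytes, int] = {}
    dup = []
    for i, row in enumerate(pos):
        key = row.tobytes()
        if key in seen:
            dup.append(i)
        else:
            seen[key] = i
    return np.array(dup, dtype=int)


def _init_positions(n: int, side: float, rng: np.random.Generator, dim: int = 3) -> np.ndarray:
    pos = rng.uniform(-side / 2.0, side / 2.0, size=(n, 3))
    if dim < 3:
        pos[:, dim:] = 0.0
    return pos


def layout_force_directed(graph: Graph, params: FRParams | None = None, *, dim: int = 3) -> Layout3D:
    """Classic 3D spring-embedder layout (adaptive budget, seeded)."""
    params = params or FRParams()
    order = sorted(graph.node_ids)
    n = len(order)
    if n == 0:
        return Layout3D({}, volume=params.volume)
    if n == 1:
        return Layout3D({order[0]: np.zeros(3)}, volume=params.volume)
    rng = np.random.default_rng(params.seed)
    pos = _init_positions(n, params.side(), rng, dim)
    pos = _fr_run(graph, order, pos, params.temperatures(n), params.k(n), params.side(), rng, dim=dim)
    return Layout3D(dict(zip(order, pos)), volume=params.volume)


# ----------------------------------------------------------------------
# Lin-log (r-PolyLog) energy layouts

@dataclass
class LinLogParams:
    """r-PolyLog energy model: r=1 is the lin-log model, r=3 matches the
    spring-embedder equilibrium.  ``edge_repulsion`` weights the
    repulsive log term by deg(u)*deg(v)."""

    r: float = 1.0
    mode: str = "node-repulsion"  # or "edge-repulsion"
    iterations: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.mode not in ("node-repulsion", "edge-repulsion"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _linlog_weights(graph: Graph, order: list[str], mode: str) -> np.ndarray:
    if mode == "node-repulsion":
        return np.ones(len(order))
    return np.array([float(graph.degree(nid)) for nid in order])


def linlog_energy(layout: Layout3D, graph: Graph, params: LinLogParams) -> float:
    """U_r(p) = sum_E (1/r)||p(u)-p(v)||^r  -  sum_pairs w_u w_v ln||p(u)-p(v)||.

    The pair sum runs over unordered distinct pairs; coincident nodes
    make the energy -inf and are rejected.
    """
    order = sorted(layout.positions)
    pos = layout.as_array(order)
    index = {nid: i for i, nid in enumerate(order)}
    w = _linlog_weights(graph, order, params.mode)
    n = len(order)
    attract = 0.0
    for e in graph.edges:
        d = float(np.linalg.norm(pos[index[e.source]] - pos[index[e.target]]))
        if d == 0.0:
            raise ValueError("coincident nodes: jitter the layout before evaluating energy")
        attract += d**params.r / params.r
    repulse = 0.0
    iu, ju = np.triu_indices(n, k=1)
    if iu.size:
        dist = np.linalg.norm(pos[iu] - pos[ju], axis=1)
        if np.any(dist == 0.0):
            raise ValueError("coincident nodes: jitter the layout before evaluating energy")
        repulse = float(np.sum(w[iu] * w[ju] * np.log(dist)))
    return attract - repulse


def _linlog_gradient(pos: np.ndarray, edges_idx: np.ndarray, w: np.ndarray, r: float) -> np.ndarray:
    n = pos.shape[0]
    grad = np.zeros_like(pos)
    if edges_idx.size:
        u, v = edges_idx[:, 0], edges_idx[:, 1]
        diff = pos[u] - pos[v]
        dist = np.maximum(np.linalg.norm(diff, axis=1), 1e-12)
        g = diff * (dist ** (r - 2.0))[:, None]
        np.add.at(grad, u, g)
        np.add.at(grad, v, -g)
    for lo, hi in _pair_chunks(n):
        diff = pos[lo:hi, None, :] - pos[None, :, :]
        dist2 = np.sum(diff * diff, axis=2)
        np.maximum(dist2, 1e-24, out=dist2)
        block = np.arange(lo, hi)
        dist2[block - lo, block] = np.inf
        coef = (w[lo:hi, None] * w[None, :]) / dist2
        grad[lo:hi] -= np.einsum("ijc,ij->ic", diff, coef)
    return grad


def layout_linlog(graph: Graph, params: LinLogParams | None = None) -> Layout3D:
    """Gradient descent on the r-PolyLog energy with step halving."""
    params = params or LinLogParams()
    order = sorted(graph.node_ids)
    n = len(order)
    if n == 0:
        return Layout3D({}, volume=1.0)
    if n == 1:
        return Layout3D({order[0]: np.zeros(3)}, volume=1.0)
    rng = np.random.default_rng(params.seed)
    side = max(2.0, 2.0 * n ** (1.0 / 3.0))
    pos = _init_positions(n, side, rng)
    index = {nid: i for i, nid in enumerate(order)}
    edges_idx = np.array([[index[e.source], index[e.target]] for e in graph.edges], dtype=int).reshape(-1, 2)
    w = _linlog_weights(graph, order, params.mode)

    def energy(p: np.ndarray) -> float:
        iu, ju = np.triu_indices(n, k=1)
        dist = np.maximum(np.linalg.norm(p[iu] - p[ju], axis=1), 1e-12)
        rep = float(np.sum(w[iu] * w[ju] * np.log(dist)))
        att = 0.0
        if edges_idx.size:
            d = np.maximum(np.linalg.norm(p[edges_idx[:, 0]] - p[edges_idx[:, 1]], axis=1), 1e-12)
            att = float(np.sum(d**params.r / params.r))
        return att - rep

    budget = params.iterations if params.iterations is not None else adaptive_iterations(n)
    step = 0.1
    e_curr = energy(pos)
    for _ in range(budget):
        grad = _linlog_gradient(pos, edges_idx, w, params.r)
        gnorm = float(np.max(np.linalg.norm(grad, axis=1)))
        if gnorm < 1e-12:
            break
        trial_step = step
        for _ in range(40):
            cand = pos - trial_step * grad / max(gnorm, 1.0)
            e_new = energy(cand)
            if e_new < e_curr:
                pos, e_curr = cand, e_new
                step = min(trial_step * 1.5, 1.0)
                break
            trial_step *= 0.5
        else:
            break
    extent = float(np.max(np.ptp(pos, axis=0))) if n > 1 else 1.0
    return Layout3D(dict(zip(order, pos)), volume=max(extent, 1e-9) ** 3)


# ----------------------------------------------------------------------
# Spectral bisection + hybrid layout

@dataclass
class BisectionResult:
    q: dict[str, int]  # +1 for part A, -1 for part B
    eigenvalue: float
    part_a: set[str]
    part_b: set[str]
    fiedler: np.ndarray | None = None  # eigenvector over sorted node ids


def _laplacian(graph: Graph, order: list[str]) -> np.ndarray:
    n = len(order)
    index = {nid: i for i, nid in enumerate(order)}
    lap = np.zeros((n, n))
    for e in graph.edges:
        i, j = index[e.source], index[e.target]
        lap[i, j] -= e.weight
        lap[j, i] -= e.weight
        lap[i, i] += e.weight
        lap[j, j] += e.weight
    return lap


def spectral_bisect(graph: Graph, *, max_iter: int = 20000, tol: float = 1e-12) -> BisectionResult:
    """Balanced bisection from the Fiedler vector of the graph Laplacian.

    Power iteration runs on the spectrally shifted matrix sigma*I - L
    (sigma from the Gershgorin bound) with the constant vector deflated,
    which makes the dominant eigenvector the Fiedler vector.  The split
    is at the median Fiedler value so |A| - |B| <= 1, ties to part A.
    """
    order = sorted(graph.node_ids)
    n = len(order)
    if n < 2:
        raise ValueError("need at least 2 nodes to bisect")
    from .graph_core import connected_components

    if len(connected_components(graph)) != 1:
        raise ValueError("graph is disconnected: bisect each component separately")
    lap = _laplacian(graph, order)
    sigma = 2.0 * float(np.max(np.diag(lap)))
    shifted = sigma * np.eye(n) - lap
    rng = np.random.default_rng(12345)  # fixed internal seed: deterministic solver
    v = rng.standard_normal(n)
    ones = np.ones(n) / math.sqrt(n)
    v -= (v @ ones) * ones
    v /= np.linalg.norm(v)
    for _ in range(max_iter):
        nxt = shifted @ v
        nxt -= (nxt @ ones) * ones
        nrm = np.linalg.norm(nxt)
        if nrm <= 1e-12 * max(sigma, 1.0):
            break  # v is annihilated by the shift: already the eigenvector
        nxt /= nrm
        if np.linalg.norm(nxt - v) < tol or np.linalg.norm(nxt + v) < tol:
            v = nxt
            break
        v = nxt
    lam = float(v @ lap @ v)
    ranked = sorted(range(n), key=lambda i: (v[i], order[i]))
    half = (n + 1) // 2
    part_a = {order[i] for i in ranked[:half]}
    part_b = set(order) - part_a
    q = {nid: (1 if nid in part_a else -1) for nid in order}
    return BisectionResult(q=q, eigenvalue=lam, part_a=part_a, part_b=part_b, fiedler=v)


def _components_halves(graph: Graph) -> tuple[set[str], set[str]]:
    from .graph_core import connected_components

    a: set[str] = set()
    b: set[str] = set()
    for comp in connected_components(graph):
        (a if len(a) <= len(b) else b).update(comp)
    return a, b


def layout_hybrid(graph: Graph, params: FRParams | None = None) -> Layout3D:
    """Bisect (Fiedler) then lay out each half independently with FR,
    offsetting the halves so their bounding boxes do not overlap."""
    params = params or FRParams()
    order = sorted(graph.node_ids)
    n = len(order)
    if n == 0:
        return Layout3D({}, volume=params.volume)
    if n == 1:
        return Layout3D({order[0]: np.zeros(3)}, volume=params.volume)
    from .graph_core import connected_components

    if len(connected_components(graph)) == 1 and n >= 2:
        res = spectral_bisect(graph)
        parts = [res.part_a, res.part_b]
    else:
        parts = list(_components_halves(graph))
    parts = [p for p in parts if p]
    sub_layouts = []
    for i, part in enumerate(parts):
        sub = graph.subgraph(part)
        sub_params = FRParams(
            volume=params.volume * len(part) / n,
            iterations=params.iterations,
            initial_step=params.initial_step,
            cooling=params.cooling,
            seed=params.seed + i,
        )
        sub_layouts.append(layout_force_directed(sub, sub_params))
    positions: dict[str, np.ndarray] = {}
    cursor = 0.0  # right edge of the previously placed part, along x
    for i, lay in enumerate(sub_layouts):
        pts = np.array(list(lay.positions.values()))
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        center = (lo + hi) / 2.0
        diameter = max(float(np.linalg.norm(hi - lo)), 1e-9)
        half_x = (hi[0] - lo[0]) / 2.0
        cx = 0.0 if i == 0 else cursor + diameter + half_x  # gap of one part-diameter
        for nid, p in lay.positions.items():
            positions[nid] = p - center + np.array([cx, 0.0, 0.0])
        cursor = cx + half_x
    return Layout3D(positions, volume=params.volume)


# ----------------------------------------------------------------------
# Multilevel coarsening

@dataclass
class CoarsenParams:
    min_size: int = 3
    rate: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.rate < 1.0):
            raise ValueError("rate must be in (0, 1)")


def _heavy_edge_matching(graph: Graph, rng: np.random.Generator) -> dict[str, str]:
    """Map each node to its merged representative via heavy-edge matching."""
    order = sorted(graph.node_ids)
    visit = list(order)
    rng.shuffle(visit)
    matched: set[str] = set()
    rep: dict[str, str] = {}
    for u in visit:
        if u in matched:
            continue
        best_v, best_w = None, -1.0
        for v, w in sorted(graph._adj[u].items()):
            if v in matched:
                continue
            if w > best_w:
                best_v, best_w = v, w
        if best_v is None:
            rep[u] = u
            matched.add(u)
        else:
            target = min(u, best_v)
            rep[u] = target
            rep[best_v] = target
            matched.update((u, best_v))
    return rep


def coarsen(graph: Graph, params: CoarsenParams | None = None) -> list[tuple[Graph, dict[str, str]]]:
    """Build a coarsening hierarchy, finest to coarsest.

    Element 0 is the input graph with an identity projection; element i
    maps level-(i-1) node ids to level-i node ids.  Halts at
    ``min_size`` nodes or when a round shrinks the graph by less than
    the coarsening rate.
    """
    from .graph_core import Edge

    params = params or CoarsenParams()
    rng = np.random.default_rng(params.seed)
    levels: list[tuple[Graph, dict[str, str]]] = [(graph, {nid: nid for nid in graph.node_ids})]
    current = graph
    while current.n > params.min_size:
        rep = _heavy_edge_matching(current, rng)
        coarse = Graph()
        for nid in sorted(set(rep.values())):
            coarse.add_node(nid)
        for e in current.edges:
            ru, rv = rep[e.source], rep[e.target]
            if ru != rv:
                coarse.add_edge(Edge(ru, rv, e.weight))
        if coarse.n >= current.n:
            break
        levels.append((coarse, rep))
        if coarse.n / current.n > params.rate or coarse.n <= params.min_size:
            break
        current = coarse
    return levels


def layout_coarsened(graph: Graph, cparams: CoarsenParams | None = None, fparams: FRParams | None = None) -> Layout3D:
    """Multilevel layout: FR on the coarsest graph, then prolongation
    with jitter and a shorter FR refinement at each finer level."""
    cparams = cparams or CoarsenParams()
    fparams = fparams or FRParams()
    if graph.n == 0:
        return Layout3D({}, volume=fparams.volume)
    levels = coarsen(graph, cparams)
    coarsest, _ = levels[-1]
    lay = layout_force_directed(coarsest, fparams)
    pos_map = dict(lay.positions)
    rng = np.random.default_rng(fparams.seed + 1)
    for level in range(len(levels) - 1, 0, -1):
        fine_graph = levels[level - 1][0]
        proj = levels[level][1]  # fine id -> coarse id
        order = sorted(fine_graph.node_ids)
        k = fparams.k(fine_graph.n)
        pos = np.array([pos_map[proj[nid]] for nid in order], dtype=float)
        pos += 0.05 * k * rng.standard_normal(pos.shape)
        budget = max(30, fparams.budget(fine_graph.n) // 4)
        t0 = (fparams.initial_step if fparams.initial_step is not None else fparams.side() / 10.0) / 2.0
        temps = t0 * (1.0 - np.arange(budget) / budget)
        pos = _fr_run(fine_graph, order, pos, temps, k, fparams.side(), rng)
        pos_map = dict(zip(order, pos))
    return Layout3D(pos_map, volume=fparams.volume)


# ----------------------------------------------------------------------
# Simulated annealing with edge cutting

@dataclass
class AnnealPhase:
    name: str
    fraction: float  # share of the total iteration budget
    temp_start: float  # in units of k
    temp_end: float
    attraction: float = 1.0


DEFAULT_PHASES = (
    AnnealPhase("liquid", 0.25, 2.0, 2.0),
    AnnealPhase("expansion", 0.25, 1.5, 1.5, attraction=0.8),
    AnnealPhase("cooldown", 0.25, 1.0, 0.5),
    AnnealPhase("crunch", 0.10, 0.4, 0.4, attraction=1.5),
    AnnealPhase("simmer", 0.15, 0.25, 0.05),
)


@dataclass
class AnnealSchedule:
    """Five-phase annealing schedule (liquid, expansion, cooldown,
    crunch, simmer).  ``edge_cut`` in [0,1]: 0 never truncates the
    attractive term (plain FR trajectory), values near 1 suppress
    attraction on the longest edges so clusters separate."""

    phases: tuple[AnnealPhase, ...] = DEFAULT_PHASES
    edge_cut: float = 0.8
    iterations: int | None = None
    volume: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.edge_cut <= 1.0):
            raise ValueError("edge_cut must be in [0, 1]")
        if not self.phases:
            raise ValueError("phase list must be non-empty")


def layout_annealed(graph: Graph, schedule: AnnealSchedule | None = None) -> Layout3D:
    schedule = schedule or AnnealSchedule()
    order = sorted(graph.node_ids)
    n = len(order)
    if n == 0:
        return Layout3D({}, volume=schedule.volume)
    if n == 1:
        return Layout3D({order[0]: np.zeros(3)}, volume=schedule.volume)
    fr = FRParams(volume=schedule.volume, iterations=schedule.iterations, seed=schedule.seed)
    budget = fr.budget(n)
    k = fr.k(n)
    if schedule.edge_cut == 0.0:
        # plain FR trajectory, same temperatures and seed as the FR engine
        temps = fr.temperatures(n)
        attraction = None
    else:
        fracs = np.array([p.fraction for p in schedule.phases])
        counts = np.maximum(1, np.round(budget * fracs / fracs.sum())).astype(int)
        counts[-1] += budget - counts.sum()
        counts[-1] = max(counts[-1], 1)
        temps_list, att_list = [], []
        for phase, cnt in zip(schedule.phases, counts):
            temps_list.append(k * np.linspace(phase.temp_start, phase.temp_end, cnt))
            att_list.append(np.full(cnt, phase.attraction))
        temps = np.concatenate(temps_list)
        attraction = np.concatenate(att_list)
    rng = np.random.default_rng(schedule.seed)
    pos = _init_positions(n, fr.side(), rng)
    pos = _fr_run(
        graph, order, pos, temps, k, fr.side(), rng,
        edge_cut=schedule.edge_cut, attraction=attraction,
    )
    return Layout3D(dict(zip(order, pos)), volume=schedule.volume)


# ----------------------------------------------------------------------
# Semantic z-levels

@dataclass
class SemanticParams:
    """Equidistant z-levels; nodes auto-binned by descending degree
    unless an explicit node -> layer mapping is supplied."""

    n_layers: int = 7
    spacing: float = 10.0
    user_layers: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")


def assign_semantic_layers(graph: Graph, params: SemanticParams | None = None) -> dict[str, int]:
    """Node -> layer index in [0, n_layers).

    User-supplied layers are honored verbatim.  The automatic rule sorts
    nodes by descending degree (ties by id) and cuts the sequence into
    ``n_layers`` contiguous bins; a cut that would fall inside a run of
    equal degrees is moved back to the start of that run when possible,
    so e.g. a star's hub occupies the top layer alone while a regular
    graph falls back to equal-size bins in id order.
    """
    params = params or SemanticParams()
    order = sorted(graph.node_ids)
    if params.user_layers is not None:
        for nid, lay in params.user_layers.items():
            if not (0 <= lay < params.n_layers):
                raise ValueError(f"layer index {lay} for node {nid!r} outside [0, {params.n_layers})")
        missing = set(order) - set(params.user_layers)
        if missing:
            raise ValueError(f"user_layers missing nodes: {sorted(missing)[:5]}")
        return dict(params.user_layers)
    n = len(order)
    if n == 0:
        return {}
    L = min(params.n_layers, n)
    ranked = sorted(order, key=lambda nid: (-graph.degree(nid), nid))
    degs = [graph.degree(nid) for nid in ranked]
    bounds = [round(j * n / L) for j in range(L + 1)]
    for j in range(1, L):
        b = bounds[j]
        if 0 < b < n and degs[b - 1] == degs[b]:
            start = b
            while start > 0 and degs[start - 1] == degs[b]:
                start -= 1
            if start > bounds[j - 1]:
                bounds[j] = start
    layers: dict[str, int] = {}
    for j in range(L):
        for idx in range(bounds[j], bounds[j + 1]):
            layers[ranked[idx]] = j
    return layers


def layout_semantic(
    graph: Graph, params: SemanticParams | None = None, fparams: FRParams | None = None
) -> Layout3D:
    """2D FR pass for x,y; z = layer * spacing exactly; each layer is
    then re-relaxed in its own plane with 20% of the global budget."""
    params = params or SemanticParams()
    fparams = fparams or FRParams(seed=params.seed)
    order = sorted(graph.node_ids)
    n = len(order)
    if n == 0:
        return Layout3D({}, volume=fparams.volume)
    layers = assign_semantic_layers(graph, params)
    base = layout_force_directed(graph, fparams, dim=2)
    rng = np.random.default_rng(fparams.seed + 7)
    positions = {nid: base.positions[nid].copy() for nid in order}
    for layer_idx in sorted(set(layers.values())):
        members = sorted(nid for nid in order if layers[nid] == layer_idx)
        if len(members) > 1:
            sub = graph.subgraph(members)
            pos = np.array([positions[nid] for nid in members])
            pos[:, 2] = 0.0
            k = fparams.k(len(members))
            budget = max(10, fparams.budget(len(members)) // 5)
            t0 = (fparams.initial_step if fparams.initial_step is not None else fparams.side() / 10.0) / 2.0
            temps = t0 * (1.0 - np.arange(budget) / budget)
            pos = _fr_run(sub, members, pos, temps, k, fparams.side(), rng, dim=2)
            for nid, p in zip(members, pos):
                positions[nid] = p
        for nid in members:
            positions[nid][2] = layers[nid] * params.spacing
    return Layout3D(positions, volume=fparams.volume)


# ----------------------------------------------------------------------
# Hemispherical layout

@dataclass
class HemisphereSpec:
    R: float = 10.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("radius must be > 0")


def sphere_point(lat_deg: float, lon_deg: float, R: float = 1.0, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Point at (latitude, longitude) on a sphere of radius R:
    x = R cos(lat) cos(lon), y = R sin(lon) cos(lat), z = R sin(lat)."""
    lat, lon = math.radians(lat_deg), math.radians(lon_deg)
    return np.array(center) + R * np.array(
        [math.cos(lat) * math.cos(lon), math.sin(lon) * math.cos(lat), math.sin(lat)]
    )


def hemisphere_position(rank: int, n: int, spec: HemisphereSpec | None = None) -> np.ndarray:
    """Position of the node of a given rank on the upper hemisphere.

    Rank 0 sits exactly at the pole (latitude 90 deg); later ranks
    descend a golden-angle spiral with uniform z spacing, which spreads
    points with near-equal area per node over the half-sphere.
    """
    spec = spec or HemisphereSpec()
    if not (0 <= rank < n):
        raise ValueError(f"rank {rank} outside [0, {n})")
    if rank == 0:
        return np.array(spec.center) + np.array([0.0, 0.0, spec.R])
    # offset of one band below the pole keeps the spiral's nearest-neighbor
    # gap uniform (the pole already claims the top band); rank n-1 reaches
    # the rim (latitude 0) exactly
    sin_lat = 1.0 - (rank + 1.0) / n
    lat = math.degrees(math.asin(sin_lat))
    lon = math.degrees((rank * GOLDEN_ANGLE) % (2.0 * math.pi))
    return sphere_point(lat, lon, spec.R, spec.center)


def layout_hemispherical(graph: Graph, spec: HemisphereSpec | None = None) -> Layout3D:
    """Degree-ranked placement on the upper hemisphere, hub at the pole."""
    spec = spec or HemisphereSpec()
    ranked = sorted(graph.node_ids, key=lambda nid: (-graph.degree(nid), nid))
    n = len(ranked)
    positions = {nid: hemisphere_position(i, n, spec) for i, nid in enumerate(ranked)}
    lay = Layout3D(positions, volume=(2.0 * spec.R) ** 3)
    lay.hemisphere = (np.array(spec.center, dtype=float), spec.R)
    return lay
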