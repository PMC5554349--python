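"""Graph data model and tabular I/O for biomolecular networks.

The in-memory model mirrors the classic interaction-network table: nodes
carry display attributes (name, color, texture, cluster, glyph size,
optional pinned 3D coordinates, signed magnitude for expression change);
edges carry a positive weight, optional color/pattern and a direction
flag.  Direction is a display attribute only — every layout, clustering
and statistic in this package treats the topology as undirected.

Readers accept tab-delimited ``.tsv``/``.txt`` and comma-delimited
``.csv`` edge tables (first two columns: source and target ids), an
optional companion node table, 3-column SIF, and ``id x y z`` coordinate
tables for physically constrained networks (e.g. residue alpha-carbon
positions).  Duplicate undirected edges are collapsed with weight
summed; self-loops are rejected with a warning recorded in the load
report.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Node",
    "Edge",
    "Graph",
    "Layout3D",
    "Partition",
    "LoadReport",
    "ParseError",
    "read_network_table",
    "read_node_table",
    "read_coordinates",
    "convert_format",
    "connected_components",
    "write_network_table",
    "write_layout_tsv",
    "write_layout_json",
    "read_partition_tsv",
    "write_partition_tsv",
]


class ParseError(ValueError):
    """Malformed input table; message carries file and line number."""


@dataclass
class Node:
    id: str
    name: str | None = None
    color: tuple[float, float, float] | None = None
    texture: str | None = None
    cluster: str | None = None
    size: float = 1.0
    coords: tuple[float, float, float] | None = None
    magnitude: float | None = None
    layer: int | None = None

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"node {self.id!r}: size must be > 0, got {self.size}")
        if self.coords is not None and not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"node {self.id!r}: non-finite coordinates {self.coords}")


@dataclass
class Edge:
    source: str
    target: str
    weight: float = 1.0
    color: tuple[float, float, float] | None = None
    directed: bool = False
    pattern: str | None = None

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(
                f"edge {self.source!r}-{self.target!r}: weight must be > 0, got {self.weight}"
            )
        if self.source == self.target:
            raise ValueError(f"self-loop on {self.source!r} is not allowed")

    @property
    def key(self) -> tuple[str, str]:
        """Canonical undirected endpoint pair (sorted)."""
        return (self.source, self.target) if self.source <= self.target else (self.target, self.source)


@dataclass
class LoadReport:
    """Bookkeeping from a table load: what was skipped or merged."""

    self_loops_skipped: int = 0
    duplicates_collapsed: int = 0
    warnings: list[str] = field(default_factory=list)


class Graph:
    """Undirected multigraph-free network with attribute-rich nodes/edges."""

    def __init__(self) -> None:
        self._nodes: dict[str, Node] = {}
        self._edges: dict[tuple[str, str], Edge] = {}
        self._adj: dict[str, dict[str, float]] = {}

    # -- construction -------------------------------------------------
    def add_node(self, node: Node | str) -> Node:
        if isinstance(node, str):
            node = Node(id=node)
        existing = self._nodes.get(node.id)
        if existing is not None:
            return existing
        self._nodes[node.id] = node
        self._adj[node.id] = {}
        return node

    def add_edge(self, edge: Edge, *, collapse: bool = True) -> Edge:
        """Insert an edge, creating endpoints as needed.

        A duplicate undirected edge is collapsed into the existing one
        with weights summed (``collapse=True``) or raises otherwise.
        """
        self.add_node(edge.source)
        self.add_node(edge.target)
        key = edge.key
        if key in self._edges:
            if not collapse:
                raise ValueError(f"duplicate edge {key}")
            kept = self._edges[key]
            kept.weight += edge.weight
            self._adj[edge.source][edge.target] = kept.weight
            self._adj[edge.target][edge.source] = kept.weight
            return kept
        self._edges[key] = edge
        self._adj[edge.source][edge.target] = edge.weight
        self._adj[edge.target][edge.source] = edge.weight
        return edge

    def remove_edge(self, u: str, v: str) -> None:
        key = (u, v) if u <= v else (v, u)
        del self._edges[key]
        del self._adj[u][v]
        del self._adj[v][u]

    # -- inspection ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self._nodes)

    @property
    def m(self) -> int:
        return len(self._edges)

    @property
    def node_ids(self) -> list[str]:
        return list(self._nodes)

    @property
    def nodes(self) -> list[Node]:
        return list(self._nodes.values())

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges.values())

    def node(self, node_id: str) -> Node:
        return self._nodes[node_id]

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def has_edge(self, u: str, v: str) -> bool:
        key = (u, v) if u <= v else (v, u)
        return key in self._edges

    def edge(self, u: str, v: str) -> Edge:
        key = (u, v) if u <= v else (v, u)
        return self._edges[key]

    def neighbors(self, node_id: str) -> list[str]:
        return list(self._adj[node_id])

    def degree(self, node_id: str) -> int:
        return len(self._adj[node_id])

    def weighted_degree(self, node_id: str) -> float:
        return float(sum(self._adj[node_id].values()))

    def total_weight(self) -> float:
        return float(sum(e.weight for e in self._edges.values()))

    def subgraph(self, node_ids: Iterable[str]) -> "Graph":
        keep = set(node_ids)
        sub = Graph()
        for nid in keep:
            sub.add_node(self._nodes[nid])
        for edge in self._edges.values():
            if edge.source in keep and edge.target in keep:
                sub.add_edge(
                    Edge(edge.source, edge.target, edge.weight, edge.color, edge.directed, edge.pattern)
                )
        return sub

    def copy(self) -> "Graph":
        return self.subgraph(self._nodes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        for e in self._edges.values():
            g.add_edge(e.source, e.target, weight=e.weight)
        return g


@dataclass
class Layout3D:
    """Node → (x, y, z) mapping inside a bounded layout volume."""

    positions: dict[str, np.ndarray]
    volume: float = 1000.0
    hemisphere: "tuple[np.ndarray, float] | None" = None  # (center, R) constraint

    def __post_init__(self) -> None:
        self.positions = {k: np.asarray(v, dtype=float) for k, v in self.positions.items()}
        for nid, p in self.positions.items():
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"position of {nid!r} must be a finite 3-vector, got {p}")

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.positions[nid] for nid in order], dtype=float)

    def centroid(self) -> np.ndarray:
        if not self.positions:
            return np.zeros(3)
        return np.mean(list(self.positions.values()), axis=0)


@dataclass
class Partition:
    """Node → cluster label, labels contiguous 0..k-1."""

    membership: dict[str, int]

    def __post_init__(self) -> None:
        labels = sorted(set(self.membership.values()))
        if labels and labels != list(range(len(labels))):
            remap = {old: new for new, old in enumerate(labels)}
            self.membership = {nid: remap[lab] for nid, lab in self.membership.items()}

    @property
    def k(self) -> int:
        return len(set(self.membership.values()))

    def clusters(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.k)]
        for nid, lab in self.membership.items():
            out[lab].add(nid)
        return out

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[str]]) -> "Partition":
        membership = {}
        for lab, group in enumerate(sets):
            for nid in group:
                membership[nid] = lab
        return cls(membership)


# ----------------------------------------------------------------------
# Readers / writers

_EDGE_COLUMNS = ("source", "target", "weight", "directed", "edge_color", "edge_pattern")
_NODE_COLUMNS = ("id", "name", "node_color", "texture", "size", "magnitude", "cluster", "layer", "x", "y", "z")


def _hex_to_rgb(token: str) -> tuple[float, float, float]:
    token = token.lstrip("#")
    if len(token) != 6:
        raise ValueError(f"expected 6-digit hex color, got {token!r}")
    return tuple(int(token[i : i + 2], 16) / 255.0 for i in (0, 2, 4))  # type: ignore[return-value]


def _rgb_to_hex(rgb: tuple[float, float, float]) -> str:
    return "#" + "".join(f"{round(c * 255):02x}" for c in rgb)


def _separator(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_network_table(path: str | Path, *, report: LoadReport | None = None) -> Graph:
    """Load an edge table (.tsv/.txt tab-separated, .csv comma-separated).

    First two columns are source and target ids.  A header row is
    recognised when the first two fields are literally ``source`` and
    ``target``; otherwise columns are positional in the order
    source, target, weight, directed, edge_color, edge_pattern.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = report if report is not None else LoadReport()
    sep = _separator(path)
    graph = Graph()
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        return graph
    columns = list(_EDGE_COLUMNS)
    start = 0
    first = [c.strip() for c in rows[0]]
    if len(first) >= 2 and first[0] == "source" and first[1] == "target":
        columns = first
        start = 1
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2:
            raise ParseError(f"{path}:{lineno}: expected at least 2 columns, got {len(row)}")
        rec = dict(zip(columns, (c.strip() for c in row)))
        src, tgt = rec["source"], rec["target"]
        if src == tgt:
            report.self_loops_skipped += 1
            report.warnings.append(f"{path}:{lineno}: self-loop on {src!r} skipped")
            continue
        try:
            weight = float(rec["weight"]) if rec.get("weight") else 1.0
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric weight {rec['weight']!r}") from exc
        if weight <= 0:
            raise ParseError(f"{path}:{lineno}: weight must be > 0, got {weight}")
        directed = rec.get("directed", "") in ("1", "true", "True")
        color = _hex_to_rgb(rec["edge_color"]) if rec.get("edge_color") else None
        pattern = rec.get("edge_pattern") or None
        if graph.has_edge(src, tgt):
            report.duplicates_collapsed += 1
        graph.add_edge(Edge(src, tgt, weight, color, directed, pattern))
    return graph


def read_node_table(path: str | Path, graph: Graph, *, report: LoadReport | None = None) -> Graph:
    """Apply a companion node-attribute table to ``graph`` in place."""
    path = Path(path)
    report = report if report is not None else LoadReport()
    sep = _separator(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        return graph
    columns = list(_NODE_COLUMNS)
    start = 0
    if rows[0] and rows[0][0].strip() == "id":
        columns = [c.strip() for c in rows[0]]
        start = 1
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if not row or not row[0].strip():
            continue
        rec = dict(zip(columns, (c.strip() for c in row)))
        nid = rec["id"]
        if not graph.has_node(nid):
            report.warnings.append(f"{path}:{lineno}: node {nid!r} not in graph, attributes ignored")
            continue
        node = graph.node(nid)
        if rec.get("name"):
            node.name = rec["name"]
        if rec.get("node_color"):
            node.color = _hex_to_rgb(rec["node_color"])
        if rec.get("texture"):
            node.texture = rec["texture"]
        if rec.get("cluster"):
            node.cluster = rec["cluster"]
        if rec.get("layer"):
            node.layer = int(rec["layer"])
        try:
            if rec.get("size"):
                node.size = float(rec["size"])
            if rec.get("magnitude"):
                node.magnitude = float(rec["magnitude"])
            if rec.get("x") or rec.get("y") or rec.get("z"):
                node.coords = (float(rec["x"]), float(rec["y"]), float(rec["z"]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if node.size <= 0:
            raise ParseError(f"{path}:{lineno}: size must be > 0")
    return graph


def read_coordinates(path: str | Path) -> tuple[dict[str, tuple[float, float, float]], list[str]]:
    """Read an ``id x y z`` table.

    Returns the mapping plus a (possibly empty) warning list; callers
    that hold a graph should cross-check ids themselves via
    :func:`coordinate_warnings`.
    """
    path = Path(path)
    sep = _separator(path)
    coords: dict[str, tuple[float, float, float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=sep), start=1):
            if not row or not row[0].strip():
                continue
            if row[0].strip() == "id":
                continue
            if len(row) < 4:
                raise ParseError(f"{path}:{lineno}: expected id x y z, got {len(row)} columns")
            nid = row[0].strip()
            try:
                xyz = tuple(float(c) for c in row[1:4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if not all(math.isfinite(c) for c in xyz):
                raise ParseError(f"{path}:{lineno}: non-finite coordinate")
            coords[nid] = xyz  # type: ignore[assignment]
    return coords, []


def coordinate_warnings(coords: Mapping[str, tuple[float, float, float]], graph: Graph) -> list[str]:
    """Ids present in a coordinate table but absent from the graph."""
    return [nid for nid in coords if not graph.has_node(nid)]


def write_network_table(graph: Graph, path: str | Path) -> None:
    sep = _separator(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(_EDGE_COLUMNS)
        for e in sorted(graph.edges, key=lambda e: e.key):
            writer.writerow(
                [
                    e.source,
                    e.target,
                    repr(e.weight) if e.weight != int(e.weight) else str(int(e.weight)) + ".0",
                    "1" if e.directed else "0",
                    _rgb_to_hex(e.color) if e.color else "",
                    e.pattern or "",
                ]
            )


def _read_sif(path: Path) -> Graph:
    graph = Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 1:
                graph.add_node(parts[0])
                continue
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: SIF line needs source, interaction, target(s)")
            src, pattern = parts[0], parts[1]
            for tgt in parts[2:]:
                if src == tgt:
                    continue
                graph.add_edge(Edge(src, tgt, 1.0, pattern=pattern))
    return graph


def _write_sif(graph: Graph, path: Path) -> list[str]:
    dropped = []
    for e in graph.edges:
        if e.weight != 1.0 or e.color is not None or e.directed:
            dropped.append(f"edge {e.source}-{e.target}: weight/color/direction not representable in SIF")
    with open(path, "w", encoding="utf-8") as fh:
        seen: set[str] = set()
        for e in sorted(graph.edges, key=lambda e: e.key):
            fh.write(f"{e.source}\t{e.pattern or 'pp'}\t{e.target}\n")
            seen.update((e.source, e.target))
        for nid in sorted(set(graph.node_ids) - seen):
            fh.write(f"{nid}\n")
    return dropped


def convert_format(in_path: str | Path, in_format: str, out_path: str | Path, out_format: str) -> list[str]:
    """Convert between SIF and native edge tables.  Returns warnings."""
    known = {"sif", "csv", "tsv"}
    if in_format not in known or out_format not in known:
        raise ValueError(f"unknown format; expected one of {sorted(known)}")
    in_path, out_path = Path(in_path), Path(out_path)
    graph = _read_sif(in_path) if in_format == "sif" else read_network_table(in_path)
    if out_format == "sif":
        return _write_sif(graph, out_path)
    write_network_table(graph, out_path)
    return []


def connected_components(graph: Graph) -> list[set[str]]:
    """Components ordered largest first, ties by smallest contained id."""
    comps = [set(c) for c in nx.connected_components(graph.to_networkx())]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def write_layout_tsv(layout: Layout3D, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tx\ty\tz\n")
        for nid in sorted(layout.positions):
            x, y, z = layout.positions[nid]
            fh.write(f"{nid}\t{x:.9g}\t{y:.9g}\t{z:.9g}\n")


def write_layout_json(graph: Graph, layout: Layout3D, path: str | Path, *, extra: dict | None = None) -> None:
    doc = {
        "nodes": [
            {
                "id": nd.id,
                "name": nd.name,
                "color": list(nd.color) if nd.color else None,
                "size": nd.size,
                "cluster": nd.cluster,
            }
            for nd in sorted(graph.nodes, key=lambda nd: nd.id)
        ],
        "edges": [
            {"source": e.source, "target": e.target, "weight": e.weight, "directed": e.directed}
            for e in sorted(graph.edges, key=lambda e: e.key)
        ],
        "positions": {nid: [float(c) for c in layout.positions[nid]] for nid in sorted(layout.positions)},
    }
    if extra:
        doc.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_partition_tsv(path: str | Path) -> Partition:
    membership: dict[str, int] = {}
    labels: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split("\t")
            if len(parts) < 2 or parts[0].strip() in ("", "id", "node"):
                continue
            lab = parts[1].strip()
            membership[parts[0].strip()] = labels.setdefault(lab, len(labels))
    return Partition(membership)


def write_partition_tsv(partition: Partition, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tcluster\n")
        for nid in sorted(partition.membership):
            fh.write(f"{nid}\t{partition.membership[nid]}\n")
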