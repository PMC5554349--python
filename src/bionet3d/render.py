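"""Headless 3D-to-2D rendering: PNG snapshots and rotation GIFs.

A painter's-algorithm renderer: nodes are shaded spherical glyphs drawn
back-to-front after a standard look-at + perspective (or orthographic)
projection; edges are straight lines or bundled polylines; cluster
bubbles draw as translucent discs; labels are flat 2D text with a 1-px
halo.  Output is byte-deterministic for fixed inputs.

Render quality (glyph tessellation, polyline segment counts, layout
iteration budgets) is a non-increasing step function of network size so
large networks stay responsive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .bundling import BundledEdge
from .cluster_layouts import BubbleLayout
from .graph_core import Graph, Layout3D

__all__ = [
    "Camera",
    "StyleSheet",
    "project",
    "render_snapshot",
    "render_rotation",
    "adaptive_quality",
]


@dataclass
class Camera:
    eye: tuple[float, float, float] = (0.0, 0.0, 60.0)
    look_at: tuple[float, float, float] = (0.0, 0.0, 0.0)
    up: tuple[float, float, float] = (0.0, 1.0, 0.0)
    field_of_view: float = 45.0  # degrees
    projection: str = "perspective"  # or "orthographic"

    def __post_init__(self) -> None:
        eye = np.asarray(self.eye, float)
        look = np.asarray(self.look_at, float)
        if np.allclose(eye, look):
            raise ValueError("camera eye must differ from look_at")
        forward = look - eye
        up = np.asarray(self.up, float)
        if np.linalg.norm(np.cross(forward, up)) < 1e-12:
            raise ValueError("up vector parallel to view direction")
        if self.projection not in ("perspective", "orthographic"):
            raise ValueError(f"unknown projection {self.projection!r}")

    @classmethod
    def fit(cls, layout: Layout3D, *, margin: float = 1.4) -> "Camera":
        """Camera looking down -z at the layout centroid from a distance
        that fits the whole layout in a 45-degree frustum."""
        center = layout.centroid()
        if layout.positions:
            pts = np.array(list(layout.positions.values()))
            radius = max(float(np.max(np.linalg.norm(pts - center, axis=1))), 1e-6)
        else:
            radius = 1.0
        dist = margin * radius / math.tan(math.radians(45.0 / 2.0))
        return cls(eye=tuple(center + np.array([0.0, 0.0, dist])), look_at=tuple(center))


@dataclass
class StyleSheet:
    background: tuple[int, int, int] = (255, 255, 255)  # white for print
    node_color: tuple[int, int, int] = (70, 110, 180)
    edge_color: tuple[int, int, int] = (120, 120, 120)
    edge_width: int = 1
    node_scale: float = 8.0  # pixels per unit glyph size at unit depth scale
    label_color: tuple[int, int, int] = (20, 20, 20)
    label_size: int = 10
    bubble_alpha: int = 60  # 0..255
    arrowheads: bool = True

    @classmethod
    def screen(cls) -> "StyleSheet":
        return cls(background=(0, 0, 0), label_color=(235, 235, 235), edge_color=(160, 160, 160))


def _view_matrix(camera: Camera) -> tuple[np.ndarray, np.ndarray]:
    eye = np.asarray(camera.eye, float)
    forward = np.asarray(camera.look_at, float) - eye
    forward /= np.linalg.norm(forward)
    right = np.cross(forward, np.asarray(camera.up, float))
    right /= np.linalg.norm(right)
    up = np.cross(right, forward)
    rot = np.stack([right, up, -forward])  # camera space: x right, y up, -z forward
    return rot, eye


def _project_points(pts: np.ndarray, camera: Camera, size: tuple[int, int]):
    rot, eye = _view_matrix(camera)
    cam = (pts - eye) @ rot.T
    depth = -cam[:, 2]  # distance along view direction
    w, h = size
    half = min(w, h) / 2.0
    f = 1.0 / math.tan(math.radians(camera.field_of_view) / 2.0)
    if camera.projection == "perspective":
        with np.errstate(divide="ignore", invalid="ignore"):
            sx = np.where(depth > 1e-9, cam[:, 0] / depth * f, np.nan)
            sy = np.where(depth > 1e-9, cam[:, 1] / depth * f, np.nan)
        scale = np.where(depth > 1e-9, f / depth * half, 0.0)
    else:
        extent = max(1e-9, float(np.max(np.abs(cam[:, :2]))) * 1.1)
        sx, sy = cam[:, 0] / extent, cam[:, 1] / extent
        scale = np.full(len(pts), half / extent)
    px = w / 2.0 + sx * half
    py = h / 2.0 - sy * half
    return np.column_stack([px, py]), depth, scale


def project(layout: Layout3D, camera: Camera, size: tuple[int, int] = (800, 800)):
    """Per-node (pixel xy, depth); points behind the eye are culled and
    listed in the returned warnings."""
    order = sorted(layout.positions)
    if not order:
        return {}, []
    pts = layout.as_array(order)
    xy, depth, _scale = _project_points(pts, camera, size)
    projected: dict[str, tuple[float, float, float]] = {}
    warnings: list[str] = []
    for nid, p, d in zip(order, xy, depth):
        if camera.projection == "perspective" and d <= 1e-9:
            warnings.append(f"node {nid!r} behind the eye, culled")
            continue
        projected[nid] = (float(p[0]), float(p[1]), float(d))
    return projected, warnings


def adaptive_quality(n: int, m: int) -> tuple[int, int, int]:
    """(sphere tessellation level, edge segment count, layout iteration
    budget) — each a non-increasing step function of network size."""
    size = max(n, m // 2)
    if size <= 100:
        tier = (4, 16)
    elif size <= 1000:
        tier = (3, 8)
    elif size <= 10_000:
        tier = (2, 4)
    elif size <= 100_000:
        tier = (1, 2)
    else:
        tier = (0, 2)
    from .layouts import adaptive_iterations

    return tier[0], tier[1], adaptive_iterations(max(n, 1))


def _draw_glyph(draw: ImageDraw.ImageDraw, x: float, y: float, r: float, color, tessellation: int) -> None:
    r = max(r, 1.0)
    box = (x - r, y - r, x + r, y + r)
    draw.ellipse(box, fill=color, outline=tuple(int(c * 0.55) for c in color[:3]) + (255,))
    if tessellation >= 2 and r >= 3:
        # cheap specular highlight sells the sphere impostor
        hr = r * 0.35
        hx, hy = x - r * 0.3, y - r * 0.3
        light = tuple(min(255, int(c + 0.6 * (255 - c))) for c in color[:3]) + (255,)
        draw.ellipse((hx - hr, hy - hr, hx + hr, hy + hr), fill=light)


def _color255(rgb: tuple[float, float, float] | None, default: tuple[int, int, int]) -> tuple[int, int, int]:
    if rgb is None:
        return default
    return tuple(int(round(c * 255)) for c in rgb)  # type: ignore[return-value]


def render_snapshot(
    graph: Graph,
    layout: Layout3D,
    path: str | None = None,
    *,
    bundles: list[BundledEdge] | None = None,
    bubbles: BubbleLayout | None = None,
    camera: Camera | None = None,
    style: StyleSheet | None = None,
    resolution: tuple[int, int] = (800, 800),
    labels: str = "none",  # none | all | top-<k>
) -> Image.Image:
    """Render one PNG snapshot; returns the image (saved if ``path``)."""
    w, h = resolution
    if w <= 0 or h <= 0:
        raise ValueError("image size must be positive")
    if max(w, h) > 20_000:
        raise ValueError("resolution capped at 20,000 px per side")
    style = style or StyleSheet()
    camera = camera or Camera.fit(layout)
    img = Image.new("RGBA", (w, h), style.background + (255,))
    draw = ImageDraw.Draw(img, "RGBA")
    order = sorted(layout.positions)
    tess, _segs, _iters = adaptive_quality(graph.n, graph.m)
    if order:
        pts = layout.as_array(order)
        xy, depth, scale = _project_points(pts, camera, (w, h))
        visible = {nid: i for i, nid in enumerate(order) if depth[i] > 1e-9}
        # bubbles first (behind everything, translucent)
        if bubbles is not None:
            labs = sorted(bubbles.centers)
            centers = np.array([bubbles.centers[lab] for lab in labs])
            cxy, cdepth, cscale = _project_points(centers, camera, (w, h))
            for i in np.argsort(-cdepth, kind="stable"):
                if cdepth[i] <= 1e-9:
                    continue
                r = bubbles.radii[labs[i]] * cscale[i]
                col = (150, 170, 220, style.bubble_alpha)
                ov = Image.new("RGBA", (w, h), (0, 0, 0, 0))
                ImageDraw.Draw(ov).ellipse(
                    (cxy[i, 0] - r, cxy[i, 1] - r, cxy[i, 0] + r, cxy[i, 1] + r), fill=col
                )
                img = Image.alpha_composite(img, ov)
            draw = ImageDraw.Draw(img, "RGBA")
        # edges, far to near by mean endpoint depth
        edge_items = []
        if bundles is not None:
            for b in bundles:
                u, v = b.edge
                if u in visible and v in visible:
                    d = (depth[visible[u]] + depth[visible[v]]) / 2.0
                    edge_items.append((d, b.points, graph.edge(u, v)))
        else:
            for e in graph.edges:
                if e.source in visible and e.target in visible:
                    i, j = visible[e.source], visible[e.target]
                    d = (depth[i] + depth[j]) / 2.0
                    seg = np.array([pts[i], pts[j]])
                    edge_items.append((d, seg, e))
        edge_items.sort(key=lambda t: -t[0])
        for _d, pline, e in edge_items:
            exy, edepth, _s = _project_points(np.asarray(pline), camera, (w, h))
            if np.any(edepth <= 1e-9):
                continue
            coords = [tuple(p) for p in exy]
            col = _color255(e.color, style.edge_color) + (255,)
            draw.line(coords, fill=col, width=style.edge_width)
            if e.directed and style.arrowheads:
                _arrowhead(draw, coords[-2], coords[-1], col)
        # nodes, far to near
        for i in np.argsort(-depth, kind="stable"):
            nid = order[i]
            if nid not in visible:
                continue
            node = graph.node(nid)
            r = style.node_scale * node.size * scale[i] / max(scale.max(), 1e-9)
            col = _color255(node.color, style.node_color) + (255,)
            _draw_glyph(draw, xy[i, 0], xy[i, 1], r, col, tess)
        _draw_labels(draw, graph, order, xy, visible, labels, style)
    out = img.convert("RGB")
    if path is not None:
        out.save(path, format="PNG")
    return out


def _arrowhead(draw, tail, tip, color, size: float = 6.0) -> None:
    dx, dy = tip[0] - tail[0], tip[1] - tail[1]
    norm = math.hypot(dx, dy)
    if norm < 1e-9:
        return
    ux, uy = dx / norm, dy / norm
    left = (tip[0] - size * (ux + 0.5 * uy), tip[1] - size * (uy - 0.5 * ux))
    right = (tip[0] - size * (ux - 0.5 * uy), tip[1] - size * (uy + 0.5 * ux))
    draw.polygon([tip, left, right], fill=color)


def _draw_labels(draw, graph: Graph, order, xy, visible, labels: str, style: StyleSheet) -> None:
    if labels == "none":
        return
    if labels == "all":
        chosen = [nid for nid in order if nid in visible]
    elif labels.startswith("top-"):
        k = int(labels.split("-", 1)[1])
        chosen = sorted(
            (nid for nid in order if nid in visible),
            key=lambda nid: (-graph.degree(nid), nid),
        )[:k]
    else:
        raise ValueError(f"unknown labels mode {labels!r}")
    font = ImageFont.load_default()
    halo = tuple(255 - c for c in style.label_color)
    for nid in chosen:
        i = visible[nid]
        text = graph.node(nid).name or nid
        x, y = xy[i, 0] + 4, xy[i, 1] - 4
        for ox, oy in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            draw.text((x + ox, y + oy), text, fill=halo + (255,), font=font)
        draw.text((x, y), text, fill=style.label_color + (255,), font=font)


def _rotate_layout(layout: Layout3D, axis: str, angle_deg: float) -> Layout3D:
    centroid = layout.centroid()
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    if axis == "x":
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    elif axis == "y":
        rot = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    elif axis == "z":
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    else:
        raise ValueError(f"axis must be x, y or z, got {axis!r}")
    return Layout3D(
        {nid: centroid + rot @ (p - centroid) for nid, p in layout.positions.items()},
        volume=layout.volume,
    )


def render_rotation(
    graph: Graph,
    layout: Layout3D,
    path: str | None = None,
    *,
    axis: str = "y",
    n_frames: int = 36,
    degrees_total: float = 360.0,
    camera: Camera | None = None,
    style: StyleSheet | None = None,
    resolution: tuple[int, int] = (400, 400),
    fps: int = 12,
) -> list[Image.Image]:
    """Rotation movie: frame f has the layout rotated by
    f * degrees_total / n_frames about the axis through the centroid."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    camera = camera or Camera.fit(layout)
    frames = []
    for f in range(n_frames):
        rotated = _rotate_layout(layout, axis, f * degrees_total / n_frames)
        frames.append(render_snapshot(graph, rotated, camera=camera, style=style, resolution=resolution))
    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(path, [np.asarray(fr) for fr in frames], extension=".gif", duration=1000 // fps, loop=0)
    return frames
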