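"""Oriented-box geometry: polygon conversion, triangulated overlap, rotated IoU.

Boxes live in image coordinates (origin top-left, x right, y down,
continuous pixels). The orientation angle ``theta`` is measured between the
box's *long* side and the x-axis, in degrees, with a 180-degree period
(the long-side convention used for elongated targets such as cereal spikes).

Overlap areas are computed by clipping one rectangle against the other
(Sutherland-Hodgman) and fan-triangulating the resulting convex
intersection polygon: the overlap is the sum of the triangle areas, which
for two rectangles is a polygon with 3 to 8 vertices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

__all__ = [
    "InvalidBoxError",
    "OrientedBox",
    "ConvexPolygon",
    "normalize_box",
    "box_to_polygon",
    "polygon_area",
    "convex_intersection",
    "rotated_iou",
    "overlap_ratio_sum",
]

# Vertices closer than this (in px) are merged; orientation tests use it too.
GEOM_EPS = 1e-9


class InvalidBoxError(ValueError):
    """Raised for degenerate boxes (non-positive side length, non-finite angle)."""


@dataclass(frozen=True)
class OrientedBox:
    """Rotated rectangle: center (cx, cy), long side w, short side h, angle theta.

    ``theta`` is the angle of the long side to the x-axis in degrees.
    ``score`` is a detection confidence in [0, 1]; ground-truth boxes leave
    it as ``None``.
    """

    cx: float
    cy: float
    w: float
    h: float
    theta: float
    cls: str = "spike"
    score: Optional[float] = None

    @property
    def area(self) -> float:
        return self.w * self.h

    def normalized(self) -> "OrientedBox":
        return normalize_box(self)


@dataclass(frozen=True)
class ConvexPolygon:
    """Convex polygon as an ordered vertex tuple, positively oriented.

    "Positively oriented" means the shoelace sum is >= 0 in the stored
    (x, y) frame; the empty polygon (no vertices) represents a void
    intersection.
    """

    vertices: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) < 3


def normalize_box(box: OrientedBox) -> OrientedBox:
    """Return an equivalent box with w >= h and theta in [0, 180).

    Swapping the two side lengths rotates the long-side direction by 90
    degrees, so the swap adds 90 to theta; theta is then wrapped into its
    180-degree period.
    """
    if not (math.isfinite(box.w) and math.isfinite(box.h) and math.isfinite(box.theta)):
        raise InvalidBoxError(f"non-finite box parameters: {box}")
    if box.w <= 0 or box.h <= 0:
        raise InvalidBoxError(f"box sides must be strictly positive, got w={box.w}, h={box.h}")
    w, h, theta = box.w, box.h, box.theta
    if w < h:
        w, h = h, w
        theta += 90.0
    theta %= 180.0
    if theta == 180.0:  # guard the -1e-16 % 180 == 180.0 float edge
        theta = 0.0
    return replace(box, w=w, h=h, theta=theta)


def box_to_polygon(box: OrientedBox) -> ConvexPolygon:
    """Corner polygon of a box, positively oriented in the stored frame."""
    b = normalize_box(box)
    t = math.radians(b.theta)
    ux, uy = math.cos(t), math.sin(t)      # unit vector along the long side
    vx, vy = -math.sin(t), math.cos(t)     # unit vector along the short side
    hw, hh = b.w / 2.0, b.h / 2.0
    return ConvexPolygon((
        (b.cx - ux * hw - vx * hh, b.cy - uy * hw - vy * hh),
        (b.cx + ux * hw - vx * hh, b.cy + uy * hw - vy * hh),
        (b.cx + ux * hw + vx * hh, b.cy + uy * hw + vy * hh),
        (b.cx - ux * hw + vx * hh, b.cy - uy * hw + vy * hh),
    ))


def _shoelace(vertices: Sequence[tuple[float, float]]) -> float:
    s = 0.0
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        s += x1 * y2 - x2 * y1
    return 0.5 * s


def polygon_area(poly: ConvexPolygon) -> float:
    """Area by fan triangulation from vertex 0.

    The polygon is split into triangles (v0, vi, vi+1); the area is the sum
    of the signed triangle areas, which for a consistently oriented convex
    polygon equals the shoelace value. Polygons with fewer than 3 vertices
    have zero area.
    """
    v = poly.vertices
    if len(v) < 3:
        return 0.0
    x0, y0 = v[0]
    total = 0.0
    for i in range(1, len(v) - 1):
        ax, ay = v[i][0] - x0, v[i][1] - y0
        bx, by = v[i + 1][0] - x0, v[i + 1][1] - y0
        total += 0.5 * (ax * by - ay * bx)
    return abs(total)


def _ensure_positive_orientation(
    vertices: Sequence[tuple[float, float]],
) -> list[tuple[float, float]]:
    verts = list(vertices)
    if _shoelace(verts) < 0:
        verts.reverse()
    return verts


def _clip_halfplane(
    subject: list[tuple[float, float]],
    a: tuple[float, float],
    b: tuple[float, float],
) -> list[tuple[float, float]]:
    """Clip polygon to the left half-plane of directed edge a->b (inclusive)."""
    ex, ey = b[0] - a[0], b[1] - a[1]

    def side(p: tuple[float, float]) -> float:
        return ex * (p[1] - a[1]) - ey * (p[0] - a[0])

    out: list[tuple[float, float]] = []
    n = len(subject)
    for i in range(n):
        cur, nxt = subject[i], subject[(i + 1) % n]
        sc, sn = side(cur), side(nxt)
        if sc >= -GEOM_EPS:
            out.append(cur)
            if sn < -GEOM_EPS:
                t = sc / (sc - sn)
                out.append((cur[0] + t * (nxt[0] - cur[0]), cur[1] + t * (nxt[1] - cur[1])))
        elif sn >= -GEOM_EPS:
            t = sc / (sc - sn)
            out.append((cur[0] + t * (nxt[0] - cur[0]), cur[1] + t * (nxt[1] - cur[1])))
    return out


def _merge_close_vertices(verts: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not verts:
        return verts
    out: list[tuple[float, float]] = []
    for p in verts:
        if out and abs(p[0] - out[-1][0]) <= GEOM_EPS and abs(p[1] - out[-1][1]) <= GEOM_EPS:
            continue
        out.append(p)
    while len(out) > 1 and abs(out[0][0] - out[-1][0]) <= GEOM_EPS and abs(out[0][1] - out[-1][1]) <= GEOM_EPS:
        out.pop()
    return out


def convex_intersection(a: ConvexPolygon, b: ConvexPolygon) -> ConvexPolygon:
    """Convex intersection of two convex polygons (Sutherland-Hodgman).

    Disjoint or merely touching inputs (shared edge or point) yield a
    degenerate polygon that is treated as empty / zero area. For two
    rectangles the non-degenerate result has 3 to 8 vertices.
    """
    subject = _ensure_positive_orientation(a.vertices)
    clipper = _ensure_positive_orientation(b.vertices)
    if len(subject) < 3 or len(clipper) < 3:
        return ConvexPolygon(())
    out = subject
    n = len(clipper)
    for i in range(n):
        out = _clip_halfplane(out, clipper[i], clipper[(i + 1) % n])
        if len(out) < 3:
            return ConvexPolygon(())
    out = _merge_close_vertices(out)
    if len(out) < 3 or polygon_area(ConvexPolygon(tuple(out))) <= GEOM_EPS:
        return ConvexPolygon(())
    return ConvexPolygon(tuple(out))


def intersection_area(a: OrientedBox, b: OrientedBox) -> float:
    """Overlap area of two oriented boxes (triangulated polygon intersection)."""
    return polygon_area(convex_intersection(box_to_polygon(a), box_to_polygon(b)))


def rotated_iou(a: OrientedBox, b: OrientedBox) -> float:
    """Intersection over union of two oriented boxes, in [0, 1]."""
    a = normalize_box(a)
    b = normalize_box(b)
    inter = intersection_area(a, b)
    union = a.area + b.area - inter
    if union <= 0:
        raise InvalidBoxError("degenerate boxes with zero union area")
    return min(inter / union, 1.0)


def overlap_ratio_sum(a: OrientedBox, b: OrientedBox) -> float:
    """Overlap area over the *sum* of the two box areas, in [0, 0.5].

    This is the duplicate-box criterion used by the oriented NMS: identical
    boxes score 0.5, disjoint boxes 0.
    """
    a = normalize_box(a)
    b = normalize_box(b)
    denom = a.area + b.area
    if denom <= 0:
        raise InvalidBoxError("degenerate boxes with zero total area")
    return intersection_area(a, b) / denom
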