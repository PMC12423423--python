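"""Annotation file formats and image tiling.

Two oriented-annotation dialects are supported:

* roLabelImg XML — one file per image; each ``<object>`` carries a
  ``<robndbox>`` with center, sides and the angle in *radians* (the tool's
  convention). Internally angles are degrees in [0, 180) with the long-side
  convention, so reading folds the tool's 360-degree angle into that range.
* DOTA-style text — one line per box: the four corner coordinates
  ``x1 y1 x2 y2 x3 y3 x4 y4`` followed by the class name and either a
  difficulty flag (ground truth) or a score (detections). Corner polygons
  are converted back to boxes via the minimum-area enclosing rotated
  rectangle.

Tiling crops a large UAV frame into fixed-size sub-images on a
non-overlapping grid whose final row/column is anchored to the image edge.
A box is assigned to the first tile (row-major) containing at least half of
its area, then clipped to the tile and re-expressed in tile coordinates.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from lxml import etree
from PIL import Image
from shapely.geometry import Polygon as ShapelyPolygon

from .containers import AnnotatedImage, DetectionSet, ImageAnnotation
from .geometry import (
    ConvexPolygon,
    OrientedBox,
    box_to_polygon,
    convex_intersection,
    normalize_box,
    polygon_area,
)

__all__ = [
    "SchemaError",
    "polygon_to_box",
    "read_rolabelimg",
    "write_rolabelimg",
    "read_dota",
    "write_dota",
    "tile_image",
    "read_image",
    "write_image",
]

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """An annotation file is parseable but missing required fields."""


def polygon_to_box(
    points: Sequence[tuple[float, float]],
    cls: str = "spike",
    score: Optional[float] = None,
) -> OrientedBox:
    """Minimum-area enclosing rotated rectangle of a point set, as a box."""
    rect = ShapelyPolygon(points).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":
        raise ValueError(f"degenerate polygon (collinear points?): {points}")
    corners = list(rect.exterior.coords)[:4]
    cx = sum(p[0] for p in corners) / 4.0
    cy = sum(p[1] for p in corners) / 4.0
    e1 = (corners[1][0] - corners[0][0], corners[1][1] - corners[0][1])
    e2 = (corners[2][0] - corners[1][0], corners[2][1] - corners[1][1])
    l1, l2 = math.hypot(*e1), math.hypot(*e2)
    if l1 >= l2:
        w, h, theta = l1, l2, math.degrees(math.atan2(e1[1], e1[0]))
    else:
        w, h, theta = l2, l1, math.degrees(math.atan2(e2[1], e2[0]))
    return normalize_box(OrientedBox(cx, cy, w, h, theta, cls=cls, score=score))


# ---------------------------------------------------------------- roLabelImg

def _xml_text(parent: etree._Element, tag: str, path: PathLike) -> str:
    el = parent.find(tag)
    if el is None or el.text is None:
        raise SchemaError(f"{path}: missing field <{tag}> under <{parent.tag}>")
    return el.text


def read_rolabelimg(path: PathLike) -> ImageAnnotation:
    """Read a roLabelImg XML annotation file (angles in radians)."""
    tree = etree.parse(str(path))  # raises XMLSyntaxError with line info
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise SchemaError(f"{path}: missing <size> element")
    W = int(float(_xml_text(size, "width", path)))
    H = int(float(_xml_text(size, "height", path)))
    image_id = Path(str(path)).stem
    fn = root.find("filename")
    if fn is not None and fn.text:
        image_id = Path(fn.text).stem
    boxes: list[OrientedBox] = []
    for obj in root.findall("object"):
        name = _xml_text(obj, "name", path)
        rb = obj.find("robndbox")
        if rb is None:
            raise SchemaError(f"{path}: <object> without <robndbox>")
        cx = float(_xml_text(rb, "cx", path))
        cy = float(_xml_text(rb, "cy", path))
        w = float(_xml_text(rb, "w", path))
        h = float(_xml_text(rb, "h", path))
        angle_rad = float(_xml_text(rb, "angle", path))
        boxes.append(
            normalize_box(OrientedBox(cx, cy, w, h, math.degrees(angle_rad), cls=name))
        )
    return ImageAnnotation(image_id, (W, H), boxes)


def write_rolabelimg(ann: ImageAnnotation, path: PathLike, depth: int = 3) -> None:
    """Write an annotation as roLabelImg XML (angles stored in radians)."""
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "."
    etree.SubElement(root, "filename").text = f"{ann.image_id}.png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(ann.image_size[0])
    etree.SubElement(size, "height").text = str(ann.image_size[1])
    etree.SubElement(size, "depth").text = str(depth)
    for box in ann.boxes:
        b = normalize_box(box)
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "type").text = "robndbox"
        etree.SubElement(obj, "name").text = b.cls
        etree.SubElement(obj, "difficult").text = "0"
        rb = etree.SubElement(obj, "robndbox")
        etree.SubElement(rb, "cx").text = f"{b.cx:.8f}"
        etree.SubElement(rb, "cy").text = f"{b.cy:.8f}"
        etree.SubElement(rb, "w").text = f"{b.w:.8f}"
        etree.SubElement(rb, "h").text = f"{b.h:.8f}"
        etree.SubElement(rb, "angle").text = f"{math.radians(b.theta):.10f}"
    Path(path).write_bytes(etree.tostring(root, pretty_print=True))


# -------------------------------------------------------------------- DOTA

def write_dota(
    obj: Union[ImageAnnotation, DetectionSet], path: PathLike, difficulty: int = 0
) -> None:
    """Write boxes as DOTA-style text (corners + class + difficulty or score)."""
    lines = []
    is_det = isinstance(obj, DetectionSet)
    for box in obj.boxes:
        b = normalize_box(box)
        verts = box_to_polygon(b).vertices
        coords = " ".join(f"{c:.8f}" for xy in verts for c in xy)
        tail = f"{b.score:.6f}" if is_det else str(difficulty)
        lines.append(f"{coords} {b.cls} {tail}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_dota(
    path: PathLike,
    detections: bool = False,
    image_id: Optional[str] = None,
    image_size: tuple[int, int] = (0, 0),
) -> Union[ImageAnnotation, DetectionSet]:
    """Read DOTA-style text; ``detections=True`` parses the tail as a score.

    The text format does not carry the image dimensions, so callers that
    need them pass ``image_size`` explicitly.
    """
    if image_id is None:
        image_id = Path(str(path)).stem
    boxes: list[OrientedBox] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("imagesource", "gsd", "#")):
            continue
        parts = line.split()
        if len(parts) != 10:
            raise SchemaError(f"{path}:{lineno}: expected 10 fields, got {len(parts)}")
        try:
            coords = [float(v) for v in parts[:8]]
            tail = float(parts[9])
        except ValueError as exc:
            raise SchemaError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
        cls = parts[8]
        pts = list(zip(coords[0::2], coords[1::2]))
        if detections:
            boxes.append(polygon_to_box(pts, cls=cls, score=tail))
        else:
            boxes.append(polygon_to_box(pts, cls=cls))
    if detections:
        return DetectionSet(image_id, image_size, boxes)
    return ImageAnnotation(image_id, image_size, boxes)


# ------------------------------------------------------------------- images

def read_image(path: PathLike) -> np.ndarray:
    """Read a PNG/JPEG image as an H x W x 3 uint8 array."""
    with Image.open(str(path)) as im:
        return np.asarray(im.convert("RGB"))


def write_image(pixels: np.ndarray, path: PathLike) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="RGB").save(str(path))


# ------------------------------------------------------------------- tiling

def _tile_origins(extent: int, tile: int) -> list[int]:
    origins = list(range(0, extent - tile + 1, tile))
    if not origins:
        origins = [0]
    if origins[-1] + tile < extent:
        origins.append(extent - tile)
    return origins


def _fit_box_inside_tile(
    vertices: Sequence[tuple[float, float]],
    tw: float,
    th: float,
    cls: str,
    score: Optional[float],
) -> Optional[OrientedBox]:
    """Min-area rotated rectangle of a clipped polygon, kept inside the tile.

    The enclosing rectangle of a clipped polygon can protrude past the tile
    edge; re-clipping and re-fitting shrinks the protrusion geometrically,
    and a final shrink about the center guards the rare non-converged case.
    """
    tile_rect = ConvexPolygon(((0.0, 0.0), (tw, 0.0), (tw, th), (0.0, th)))
    tol = 1e-7
    verts = list(vertices)
    box: Optional[OrientedBox] = None
    for _ in range(50):
        try:
            box = polygon_to_box(verts, cls=cls, score=score)
        except ValueError:
            return None
        corners = box_to_polygon(box).vertices
        if all(-tol <= x <= tw + tol and -tol <= y <= th + tol for x, y in corners):
            return box
        clipped = convex_intersection(ConvexPolygon(tuple(corners)), tile_rect)
        if clipped.is_empty:
            return None
        verts = list(clipped.vertices)
    from dataclasses import replace as _replace

    for _ in range(200):
        box = _replace(box, w=box.w * 0.999, h=box.h * 0.999)
        corners = box_to_polygon(box).vertices
        if all(-tol <= x <= tw + tol and -tol <= y <= th + tol for x, y in corners):
            return box
    return None


def tile_image(img: AnnotatedImage, tile: tuple[int, int] = (600, 600)) -> list[AnnotatedImage]:
    """Crop an annotated image into tile-sized sub-images with clipped boxes.

    Tiles are laid on a non-overlapping grid with stride equal to the tile
    size; the final row and column are anchored to the image edge (they may
    overlap their predecessors). Each box goes to the first tile (row-major
    order) holding at least 50% of its area, clipped to the tile and
    re-fitted as the minimum-area rotated rectangle in tile coordinates.
    """
    tw, th = tile
    W, H = img.size
    if tw > W or th > H:
        raise ValueError(f"tile {tile} larger than image {(W, H)}")
    xs = _tile_origins(W, tw)
    ys = _tile_origins(H, th)

    assignments: dict[tuple[int, int], list[OrientedBox]] = {}
    for box in img.annotation.boxes:
        b = normalize_box(box)
        poly = box_to_polygon(b)
        area = b.area
        for y0 in ys:
            placed = False
            for x0 in xs:
                rect = ConvexPolygon((
                    (x0, y0), (x0 + tw, y0), (x0 + tw, y0 + th), (x0, y0 + th),
                ))
                clipped = convex_intersection(poly, rect)
                if polygon_area(clipped) >= 0.5 * area - 1e-9:
                    local = [(x - x0, y - y0) for x, y in clipped.vertices]
                    nb = _fit_box_inside_tile(local, tw, th, b.cls, b.score)
                    if nb is not None:
                        assignments.setdefault((x0, y0), []).append(nb)
                    placed = True
                    break
            if placed:
                break

    out: list[AnnotatedImage] = []
    for r, y0 in enumerate(ys):
        for c, x0 in enumerate(xs):
            pixels = img.pixels[y0:y0 + th, x0:x0 + tw].copy()
            ann = ImageAnnotation(
                f"{img.image_id}_r{r}_c{c}", (tw, th), assignments.get((x0, y0), [])
            )
            out.append(AnnotatedImage(pixels, ann))
    return out
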