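"""Geometry: normalization, polygon conversion, triangulated overlap, rotated IoU.

The clipping/triangulation implementation is checked against two
independent routes: shapely's polygon intersection and a rasterization
(point-counting) oracle.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon as ShapelyPolygon

from spikekit.geometry import (
    ConvexPolygon,
    InvalidBoxError,
    OrientedBox,
    box_to_polygon,
    convex_intersection,
    normalize_box,
    overlap_ratio_sum,
    polygon_area,
    rotated_iou,
)
from spikekit.synthetic import rasterized_iou_oracle

from conftest import random_box


def _shoelace(verts):
    n = len(verts)
    return abs(sum(verts[i][0] * verts[(i + 1) % n][1] - verts[(i + 1) % n][0] * verts[i][1]
                   for i in range(n))) / 2.0


class TestNormalizeBox:
    @pytest.mark.parametrize(
        "box, expected",
        [
            ((0, 0, 2, 6, 10), (0, 0, 6, 2, 100.0)),   # side swap adds 90
            ((0, 0, 6, 2, 190), (0, 0, 6, 2, 10.0)),   # period-180 wrap
            ((0, 0, 6, 2, 45), (0, 0, 6, 2, 45.0)),    # already normalized
            ((3, 4, 1, 5, -30), (3, 4, 5, 1, 60.0)),
        ],
    )
    def test_examples(self, box, expected):
        nb = normalize_box(OrientedBox(*box))
        assert (nb.cx, nb.cy, nb.w, nb.h, nb.theta) == pytest.approx(expected)

    @pytest.mark.parametrize("w,h", [(0, 2), (2, 0), (-1, 2), (2, -3)])
    def test_nonpositive_sides_rejected(self, w, h):
        with pytest.raises(InvalidBoxError):
            normalize_box(OrientedBox(0, 0, w, h, 0))

    @given(theta=st.floats(-720, 720), w=st.floats(0.5, 50), h=st.floats(0.5, 50))
    @settings(max_examples=100, derandomize=True)
    def test_invariants_and_same_point_set(self, theta, w, h):
        nb = normalize_box(OrientedBox(1.0, -2.0, w, h, theta))
        assert nb.w >= nb.h and 0 <= nb.theta < 180

        # corners of the raw box, computed independently of the library
        t = math.radians(theta)
        u, v = (math.cos(t), math.sin(t)), (-math.sin(t), math.cos(t))
        raw = ShapelyPolygon([
            (1.0 + su * u[0] * w / 2 + sv * v[0] * h / 2,
             -2.0 + su * u[1] * w / 2 + sv * v[1] * h / 2)
            for su, sv in ((-1, -1), (1, -1), (1, 1), (-1, 1))
        ])
        norm = ShapelyPolygon(box_to_polygon(nb).vertices)
        assert raw.symmetric_difference(norm).area < 1e-6 * raw.area


class TestBoxToPolygon:
    def test_axis_aligned(self):
        verts = set(map(lambda p: (round(p[0], 9), round(p[1], 9)),
                        box_to_polygon(OrientedBox(0, 0, 4, 2, 0)).vertices))
        assert verts == {(-2, -1), (2, -1), (2, 1), (-2, 1)}

    def test_quarter_turn(self):
        verts = set(map(lambda p: (round(p[0], 9), round(p[1], 9)),
                        box_to_polygon(OrientedBox(0, 0, 4, 2, 90)).vertices))
        assert verts == {(-1, -2), (1, -2), (1, 2), (-1, 2)}

    def test_diagonal_square(self):
        poly = box_to_polygon(OrientedBox(5, 5, 2, 2, 45))
        for x, y in poly.vertices:
            assert math.hypot(x - 5, y - 5) == pytest.approx(math.sqrt(2))
        # vertices lie on the axis-parallel diagonals through the center
        assert any(abs(x - 5) < 1e-9 for x, y in poly.vertices)

    def test_centroid_and_edge_lengths(self, rng):
        for _ in range(20):
            b = random_box(rng)
            v = box_to_polygon(b).vertices
            assert np.mean([p[0] for p in v]) == pytest.approx(b.cx)
            assert np.mean([p[1] for p in v]) == pytest.approx(b.cy)
            lengths = sorted(
                math.dist(v[i], v[(i + 1) % 4]) for i in range(4)
            )
            assert lengths == pytest.approx(sorted([b.w, b.w, b.h, b.h]))


class TestPolygonArea:
    @pytest.mark.parametrize(
        "verts, expected",
        [
            (((0, 0), (1, 0), (0, 1)), 0.5),
            (((0, 0), (1, 0), (1, 1), (0, 1)), 1.0),
            ((), 0.0),
            (((0, 0), (1, 1)), 0.0),
        ],
    )
    def test_examples(self, verts, expected):
        assert polygon_area(ConvexPolygon(verts)) == pytest.approx(expected)

    def test_regular_hexagon_closed_form(self):
        verts = tuple(
            (math.cos(2 * math.pi * k / 6), math.sin(2 * math.pi * k / 6)) for k in range(6)
        )
        assert polygon_area(ConvexPolygon(verts)) == pytest.approx(3 * math.sqrt(3) / 2, abs=1e-12)

    def test_fan_equals_shoelace_on_intersections(self, rng):
        for _ in range(200):
            a, b = random_box(rng), random_box(rng)
            inter = convex_intersection(box_to_polygon(a), box_to_polygon(b))
            if inter.is_empty:
                continue
            fan = polygon_area(inter)
            assert fan == pytest.approx(_shoelace(inter.vertices), rel=1e-9, abs=1e-12)


class TestConvexIntersection:
    def test_offset_unit_squares(self):
        sq = lambda x0: ConvexPolygon(((x0, x0), (x0 + 2, x0), (x0 + 2, x0 + 2), (x0, x0 + 2)))
        inter = convex_intersection(sq(0), sq(1))
        assert polygon_area(inter) == pytest.approx(1.0)
        assert set(map(lambda p: (round(p[0], 9), round(p[1], 9)), inter.vertices)) == {
            (1, 1), (2, 1), (2, 2), (1, 2)}

    def test_disjoint_is_empty(self):
        a = box_to_polygon(OrientedBox(0, 0, 2, 2, 0))
        b = box_to_polygon(OrientedBox(10, 0, 2, 2, 30))
        assert convex_intersection(a, b).is_empty

    def test_touching_edge_counts_as_empty(self):
        a = box_to_polygon(OrientedBox(0, 0, 2, 2, 0))
        b = box_to_polygon(OrientedBox(2, 0, 2, 2, 0))
        assert polygon_area(convex_intersection(a, b)) == 0.0

    def test_rotated_square_octagon(self):
        # square side 2 vs itself rotated 45 deg: regular octagon, area 8(sqrt2 - 1)
        a = box_to_polygon(OrientedBox(0, 0, 2, 2, 0))
        b = box_to_polygon(OrientedBox(0, 0, 2, 2, 45))
        inter = convex_intersection(a, b)
        assert len(inter) == 8
        assert polygon_area(inter) == pytest.approx(8 * (math.sqrt(2) - 1), abs=1e-9)

    def test_vertex_count_bounded_by_eight(self, rng):
        for _ in range(300):
            a, b = random_box(rng), random_box(rng)
            inter = convex_intersection(box_to_polygon(a), box_to_polygon(b))
            assert len(inter) <= 8

    def test_matches_shapely_intersection_area(self, rng):
        """Independent route: shapely polygon intersection on random pairs."""
        for _ in range(300):
            a, b = random_box(rng), random_box(rng)
            pa, pb = box_to_polygon(a), box_to_polygon(b)
            ours = polygon_area(convex_intersection(pa, pb))
            ref = ShapelyPolygon(pa.vertices).intersection(ShapelyPolygon(pb.vertices)).area
            assert ours == pytest.approx(ref, abs=1e-6)


class TestRotatedIoU:
    def test_identical_boxes(self, rng):
        b = random_box(rng)
        assert rotated_iou(b, b) == pytest.approx(1.0)

    def test_offset_squares_analytic(self):
        assert rotated_iou(OrientedBox(0, 0, 2, 2, 0), OrientedBox(1, 0, 2, 2, 0)) == pytest.approx(1 / 3)

    def test_rotated_square_closed_form(self):
        # area(octagon) / (8 - area(octagon)) = (sqrt2-1)/(2-sqrt2) = 1/sqrt2
        got = rotated_iou(OrientedBox(0, 0, 2, 2, 0), OrientedBox(0, 0, 2, 2, 45))
        assert got == pytest.approx(1 / math.sqrt(2), abs=1e-9)

    def test_symmetry(self, rng):
        for _ in range(50):
            a, b = random_box(rng), random_box(rng)
            assert rotated_iou(a, b) == pytest.approx(rotated_iou(b, a), abs=1e-12)
            assert overlap_ratio_sum(a, b) == pytest.approx(overlap_ratio_sum(b, a), abs=1e-12)

    def test_rigid_transform_invariance(self, rng):
        def transform(box, dx, dy, rot):
            t = math.radians(rot)
            x = box.cx * math.cos(t) - box.cy * math.sin(t) + dx
            y = box.cx * math.sin(t) + box.cy * math.cos(t) + dy
            return normalize_box(OrientedBox(x, y, box.w, box.h, box.theta + rot))

        for _ in range(30):
            a, b = random_box(rng), random_box(rng)
            base = rotated_iou(a, b)
            dx, dy, rot = rng.uniform(-500, 500, 2).tolist() + [rng.uniform(0, 360)]
            moved = rotated_iou(transform(a, dx, dy, rot), transform(b, dx, dy, rot))
            assert moved == pytest.approx(base, abs=1e-9)

    def test_against_rasterization_oracle(self, rng):
        """Spot check at high resolution; the full 500-pair sweep runs in the
        acceptance suite."""
        for _ in range(25):
            a, b = random_box(rng), random_box(rng)
            assert abs(rotated_iou(a, b) - rasterized_iou_oracle(a, b, 800)) <= 0.01

    @given(data=st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_iou_bounds_property(self, data):
        def draw_box(label):
            return normalize_box(OrientedBox(
                data.draw(st.floats(-30, 30), label=f"{label}x"),
                data.draw(st.floats(-30, 30), label=f"{label}y"),
                data.draw(st.floats(1, 60), label=f"{label}w"),
                data.draw(st.floats(1, 60), label=f"{label}h"),
                data.draw(st.floats(0, 180, exclude_max=True), label=f"{label}t"),
            ))
        a, b = draw_box("a"), draw_box("b")
        iou = rotated_iou(a, b)
        assert 0.0 <= iou <= 1.0
        s = overlap_ratio_sum(a, b)
        assert 0.0 <= s <= 0.5 + 1e-12


class TestOverlapRatioSum:
    def test_identical_is_half(self, rng):
        b = random_box(rng)
        assert overlap_ratio_sum(b, b) == pytest.approx(0.5)

    def test_disjoint_is_zero(self):
        assert overlap_ratio_sum(OrientedBox(0, 0, 2, 2, 0), OrientedBox(100, 0, 2, 2, 17)) == 0.0

    def test_offset_squares_analytic(self):
        assert overlap_ratio_sum(OrientedBox(0, 0, 2, 2, 0), OrientedBox(1, 0, 2, 2, 0)) == pytest.approx(0.25)
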