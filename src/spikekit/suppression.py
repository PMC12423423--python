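"""Duplicate-detection removal (oriented NMS).

Dense elongated targets produce clusters of near-coincident oriented
detections. Greedy non-maximum suppression keeps the highest-scored box of
each cluster and discards any remaining box whose overlap with a kept box
exceeds a threshold. The overlap criterion is the ratio of the overlap area
to the *sum* of the two box areas (0.5 for identical boxes, 0 for disjoint
ones); the conventional IoU criterion is available as an alternative.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Literal

from .containers import DetectionSet
from .geometry import normalize_box, overlap_ratio_sum, rotated_iou

__all__ = ["oriented_nms", "DEFAULT_SUM_RATIO_THRESHOLD"]

Criterion = Literal["sum-ratio", "iou"]

# Half of the sum-ratio's 0.5 maximum, analogous to the customary IoU 0.5.
DEFAULT_SUM_RATIO_THRESHOLD = 0.25


def oriented_nms(
    dets: DetectionSet,
    overlap_threshold: float = DEFAULT_SUM_RATIO_THRESHOLD,
    criterion: Criterion = "sum-ratio",
) -> DetectionSet:
    """Greedy score-descending suppression of duplicate oriented boxes.

    The highest-scored box is kept; every remaining box whose overlap
    criterion with a kept box exceeds ``overlap_threshold`` is discarded;
    repeat. Output is score-descending and a subset of the input. Ties in
    score are broken by box geometry so the kept set does not depend on
    input order.
    """
    if criterion == "sum-ratio":
        if not 0.0 < overlap_threshold <= 0.5:
            raise ValueError(
                f"sum-ratio threshold must be in (0, 0.5], got {overlap_threshold}"
            )
        overlap = overlap_ratio_sum
    elif criterion == "iou":
        if not 0.0 < overlap_threshold <= 1.0:
            raise ValueError(f"iou threshold must be in (0, 1], got {overlap_threshold}")
        overlap = rotated_iou
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    boxes = sorted(
        (normalize_box(b) for b in dets.boxes),
        key=lambda b: (-b.score, b.cx, b.cy, b.w, b.h, b.theta),
    )
    kept: list = []
    for cand in boxes:
        if all(overlap(cand, k) <= overlap_threshold for k in kept):
            kept.append(cand)
    return replace(dets, boxes=kept)
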