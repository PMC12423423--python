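"""Wise-IoU localization loss (forward evaluation).

The plain IoU loss ``1 - IoU`` treats every assigned prediction equally.
The Wise-IoU variant multiplies each pair's IoU loss by a focusing factor

    alpha = exp( ((GT_x - B_x)^2 + (GT_y - B_y)^2) / (GT_w + GT_h)^2 )

driven by the squared center distance normalized by the ground-truth box
size, so badly mislocated predictions are penalized more than well-centred
ones. alpha >= 1 with equality exactly when the centers coincide.

This module evaluates the loss for an explicit list of assigned
(prediction, ground truth) pairs; anchor assignment and gradients are out
of scope (the assignment indicator is realized by the pair list itself).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

from .geometry import InvalidBoxError, OrientedBox, normalize_box, rotated_iou

__all__ = ["AssignedPair", "wiou_alpha", "iou_loss_term", "wise_iou_loss", "horizontal_iou"]

IouMode = Literal["horizontal", "rotated"]


@dataclass(frozen=True)
class AssignedPair:
    """One ground-truth box and the prediction assigned to it.

    ``iou_mode`` selects the IoU used by the loss: ``"horizontal"``
    (default) measures overlap of the decoupled axis-aligned (x, y, w, h)
    boxes, matching a pipeline in which the angle is handled by
    classification; ``"rotated"`` uses the full oriented-box IoU.
    """

    gt: OrientedBox
    pred: OrientedBox
    iou_mode: IouMode = "horizontal"


def horizontal_iou(a: OrientedBox, b: OrientedBox) -> float:
    """IoU of the axis-aligned (cx, cy, w, h) decoupling of two boxes."""
    a = normalize_box(a)
    b = normalize_box(b)
    ix = max(
        0.0,
        min(a.cx + a.w / 2, b.cx + b.w / 2) - max(a.cx - a.w / 2, b.cx - b.w / 2),
    )
    iy = max(
        0.0,
        min(a.cy + a.h / 2, b.cy + b.h / 2) - max(a.cy - a.h / 2, b.cy - b.h / 2),
    )
    inter = ix * iy
    union = a.area + b.area - inter
    if union <= 0:
        raise InvalidBoxError("degenerate boxes with zero union area")
    return inter / union


def wiou_alpha(pair: AssignedPair) -> float:
    """Focusing factor exp(center distance^2 / (GT_w + GT_h)^2), >= 1."""
    gt = normalize_box(pair.gt)
    pred = normalize_box(pair.pred)
    denom = gt.w + gt.h
    if denom <= 0:
        raise InvalidBoxError("ground-truth box has zero size")
    d2 = (gt.cx - pred.cx) ** 2 + (gt.cy - pred.cy) ** 2
    return math.exp(d2 / denom ** 2)


def _pair_iou(pair: AssignedPair) -> float:
    if pair.iou_mode == "rotated":
        return rotated_iou(pair.gt, pair.pred)
    return horizontal_iou(pair.gt, pair.pred)


def iou_loss_term(pair: AssignedPair) -> float:
    """Per-pair IoU loss: 1 - IoU(gt, pred), in [0, 1]."""
    return 1.0 - _pair_iou(pair)


def wise_iou_loss(pairs: Iterable[AssignedPair]) -> tuple[float, list[float]]:
    """Total Wise-IoU loss over assigned pairs, with per-pair breakdown.

    Returns ``(total, per_pair)`` where each per-pair term is
    ``alpha * (1 - IoU)``. An empty pair list yields 0 with a warning.
    """
    per_pair = [wiou_alpha(p) * iou_loss_term(p) for p in pairs]
    if not per_pair:
        warnings.warn("wise_iou_loss called with no assigned pairs; returning 0", stacklevel=2)
        return 0.0, []
    return sum(per_pair), per_pair
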