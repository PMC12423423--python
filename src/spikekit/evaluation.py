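"""Detection, angle and count metrics for oriented-box predictions.

Five metrics are computed for a prediction/ground-truth pairing:

* mAP — area under the precision-recall curve, P = TP/(TP+FP) and
  R = TP/(TP+FN), integrated over recall 0..1 with all-points
  interpolation. With a single class mAP equals the class AP.
* RMSE_a / MAE_a — root-mean-square and mean absolute error of the
  long-side angle over matched (true positive) pairs, pooled across
  images. Angle differences use the 180-degree circular distance by
  default, so 179 deg vs 1 deg counts as 2 deg.
* RMSE / MAE — per-image spike-count errors between the number of
  annotated boxes a_i and the number of predicted boxes t_i.

Matching is greedy: predictions in descending score order claim the
unmatched ground-truth box of highest rotated IoU above the threshold;
unclaimed predictions are false positives, unclaimed ground truths false
negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from .containers import DetectionSet, ImageAnnotation
from .csl import circular_angle_distance
from .geometry import OrientedBox, normalize_box, rotated_iou

__all__ = [
    "UndefinedMetricError",
    "MatchResult",
    "EvalReport",
    "match_detections",
    "precision_recall_curve",
    "average_precision",
    "angle_errors",
    "count_errors",
    "evaluate",
]

DEFAULT_MATCH_IOU = 0.5


class UndefinedMetricError(ValueError):
    """A metric has no defined value (e.g. angle error with zero matches)."""


@dataclass
class MatchResult:
    """TP/FP/FN partition of one image's predictions."""

    image_id: str
    pairs: list[tuple[OrientedBox, OrientedBox, float]]  # (pred, gt, iou)
    unmatched_preds: list[OrientedBox]  # false positives
    unmatched_gts: list[OrientedBox]  # false negatives

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_preds)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gts)


@dataclass
class EvalReport:
    """All five metrics plus the PR curve and per-image counts."""

    map: float
    pr_curve: list[tuple[float, float]]  # (recall, precision) points
    rmse_a: Optional[float]
    mae_a: Optional[float]
    rmse: float
    mae: float
    n_images: int
    per_image: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "map": self.map,
            "rmse_a": self.rmse_a,
            "mae_a": self.mae_a,
            "rmse": self.rmse,
            "mae": self.mae,
            "n_images": self.n_images,
            "pr_curve": [[r, p] for r, p in self.pr_curve],
            "per_image": self.per_image,
        }


def match_detections(
    preds: DetectionSet,
    gts: ImageAnnotation,
    iou_threshold: float = DEFAULT_MATCH_IOU,
) -> MatchResult:
    """Greedily match scored predictions to ground-truth boxes by rotated IoU."""
    if preds.image_id != gts.image_id:
        raise ValueError(
            f"prediction image {preds.image_id!r} != ground-truth image {gts.image_id!r}"
        )
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError(f"iou threshold must be in (0, 1), got {iou_threshold}")
    gt_boxes = [normalize_box(g) for g in gts.boxes]
    taken = [False] * len(gt_boxes)
    pairs: list[tuple[OrientedBox, OrientedBox, float]] = []
    fps: list[OrientedBox] = []
    for pred in sorted(preds.boxes, key=lambda b: -b.score):
        pred = normalize_box(pred)
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gt_boxes):
            if taken[j]:
                continue
            iou = rotated_iou(pred, gt)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            pairs.append((pred, gt_boxes[best_j], best_iou))
        else:
            fps.append(pred)
    fns = [g for g, t in zip(gt_boxes, taken) if not t]
    return MatchResult(preds.image_id, pairs, fps, fns)


def matches_from_correspondence(
    preds: DetectionSet, gts: ImageAnnotation
) -> MatchResult:
    """MatchResult from a known 1:1 prediction/ground-truth correspondence.

    For synthetic detections derived from ground truth with identity
    preserved (same box order, no misses or spurious boxes), this bypasses
    IoU matching entirely: it pairs boxes positionally. Useful when
    measuring metric recovery of injected noise, where threshold-based
    matching would censor the large-error tail.
    """
    if preds.image_id != gts.image_id:
        raise ValueError(
            f"prediction image {preds.image_id!r} != ground-truth image {gts.image_id!r}"
        )
    if len(preds.boxes) != len(gts.boxes):
        raise ValueError(
            f"correspondence needs equal box counts, got {len(preds.boxes)} vs {len(gts.boxes)}"
        )
    pairs = [
        (normalize_box(p), normalize_box(g), rotated_iou(p, g))
        for p, g in zip(preds.boxes, gts.boxes)
    ]
    return MatchResult(preds.image_id, pairs, [], [])


def _ranked_hits(matches: Iterable[MatchResult]) -> tuple[list[tuple[float, bool]], int]:
    """Pool all predictions across images as (score, is_tp), plus total GT count."""
    hits: list[tuple[float, bool]] = []
    n_gt = 0
    for m in matches:
        n_gt += m.tp + m.fn
        hits.extend((p.score, True) for p, _, _ in m.pairs)
        hits.extend((p.score, False) for p in m.unmatched_preds)
    hits.sort(key=lambda h: -h[0])
    return hits, n_gt


def precision_recall_curve(matches: Iterable[MatchResult]) -> list[tuple[float, float]]:
    """Cumulative (recall, precision) points in descending score order.

    One point per prediction: after the k highest-scored predictions,
    P = TP_k / k and R = TP_k / n_gt.
    """
    hits, n_gt = _ranked_hits(matches)
    points: list[tuple[float, float]] = []
    tp = 0
    for k, (_, is_tp) in enumerate(hits, start=1):
        if is_tp:
            tp += 1
        recall = tp / n_gt if n_gt else 0.0
        points.append((recall, tp / k))
    return points


def average_precision(
    curve: Sequence[tuple[float, float]],
    method: Literal["all-points", "11-point"] = "all-points",
) -> float:
    """Area under the precision-recall curve.

    ``all-points`` (default) integrates the interpolated envelope: the
    precision at recall r is the maximum precision attained at any recall
    >= r. ``11-point`` averages the interpolated precision at recalls
    0, 0.1, ..., 1.0 for comparability with older benchmarks.
    """
    if not curve:
        return 0.0
    pts = sorted(curve)  # ascending recall
    recalls = [r for r, _ in pts]
    # interpolated precision: running max from the high-recall end
    interp: list[float] = [0.0] * len(pts)
    running = 0.0
    for i in range(len(pts) - 1, -1, -1):
        running = max(running, pts[i][1])
        interp[i] = running
    if method == "11-point":
        total = 0.0
        for r in [i / 10 for i in range(11)]:
            js = [j for j, rr in enumerate(recalls) if rr >= r]
            total += interp[js[0]] if js else 0.0
        return total / 11.0
    if method != "all-points":
        raise ValueError(f"unknown AP method {method!r}")
    ap = 0.0
    prev_r = 0.0
    for j, r in enumerate(recalls):
        if r > prev_r:
            ap += (r - prev_r) * interp[j]
            prev_r = r
    return ap


def angle_errors(
    matches: Iterable[MatchResult],
    circular: bool = True,
    per_image_mean: bool = False,
) -> tuple[float, float]:
    """(RMSE_a, MAE_a) of matched-pair angles, in degrees.

    Pooled over all matched pairs of all images by default; with
    ``per_image_mean`` the squared/absolute errors are first averaged
    within each image and the F per-image means are then aggregated.
    ``circular=False`` uses the raw signed difference p - q instead of the
    180-degree circular distance (kept for parity with the printed
    formulas, but it inflates errors near the period boundary).
    """
    groups: list[list[float]] = []
    for m in matches:
        errs = []
        for pred, gt, _ in m.pairs:
            if circular:
                errs.append(circular_angle_distance(pred.theta, gt.theta))
            else:
                errs.append(pred.theta - gt.theta)
        if errs:
            groups.append(errs)
    if not groups:
        raise UndefinedMetricError("angle metrics need at least one matched pair")
    if per_image_mean:
        sq = [sum(e * e for e in g) / len(g) for g in groups]
        ab = [sum(abs(e) for e in g) / len(g) for g in groups]
        return math.sqrt(sum(sq) / len(sq)), sum(ab) / len(ab)
    flat = [e for g in groups for e in g]
    rmse = math.sqrt(sum(e * e for e in flat) / len(flat))
    mae = sum(abs(e) for e in flat) / len(flat)
    return rmse, mae


def count_errors(counts: Sequence[tuple[int, int]]) -> tuple[float, float]:
    """(RMSE, MAE) of per-image spike counts.

    ``counts`` holds one (a_i, t_i) pair per image: a_i annotated boxes,
    t_i predicted boxes.
    """
    if not counts:
        raise UndefinedMetricError("count metrics need at least one image")
    diffs = [a - t for a, t in counts]
    rmse = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    mae = sum(abs(d) for d in diffs) / len(diffs)
    return rmse, mae


def evaluate(
    preds: Sequence[DetectionSet],
    gts: Sequence[ImageAnnotation],
    iou_threshold: float = DEFAULT_MATCH_IOU,
    score_threshold: float = 0.0,
    circular_angles: bool = True,
) -> EvalReport:
    """Full evaluation of a prediction set against ground truth.

    Predictions and ground truths are paired by ``image_id`` (every
    prediction image must have a ground-truth annotation). The PR curve and
    mAP rank all predictions by score; the per-image counts t_i include
    only predictions with score >= ``score_threshold``.
    """
    gt_by_id = {g.image_id: g for g in gts}
    if len(gt_by_id) != len(gts):
        raise ValueError("duplicate ground-truth image ids")
    pred_by_id = {p.image_id: p for p in preds}
    missing = set(pred_by_id) - set(gt_by_id)
    if missing:
        raise ValueError(f"predictions for unknown images: {sorted(missing)}")

    matches: list[MatchResult] = []
    counts: list[tuple[int, int]] = []
    per_image: list[dict] = []
    for image_id, gt in gt_by_id.items():
        pred = pred_by_id.get(image_id, DetectionSet(image_id, gt.image_size, []))
        m = match_detections(pred, gt, iou_threshold)
        matches.append(m)
        t_i = sum(1 for b in pred.boxes if b.score >= score_threshold)
        a_i = len(gt.boxes)
        counts.append((a_i, t_i))
        per_image.append(
            {"image_id": image_id, "labeled": a_i, "predicted": t_i,
             "tp": m.tp, "fp": m.fp, "fn": m.fn}
        )

    curve = precision_recall_curve(matches)
    ap = average_precision(curve)
    try:
        rmse_a, mae_a = angle_errors(matches, circular=circular_angles)
    except UndefinedMetricError:
        rmse_a = mae_a = None
    rmse, mae = count_errors(counts)
    return EvalReport(
        map=ap,
        pr_curve=curve,
        rmse_a=rmse_a,
        mae_a=mae_a,
        rmse=rmse,
        mae=mae,
        n_images=len(gt_by_id),
        per_image=per_image,
    )
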