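"""Detection evaluation: IoU, confidence-greedy matching, precision/recall,
interpolated average precision and mAP@50-95.

Matching is greedy in descending confidence (ties: input index); each
prediction takes the unmatched ground truth of highest IoU at or above the
threshold.  AP uses the all-point precision-envelope interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Mapping, Sequence, Tuple

import numpy as np

from .geometry import PixelBox

__all__ = [
    "Detection",
    "MatchResult",
    "PRCurve",
    "MapConfig",
    "iou",
    "match_detections",
    "precision",
    "recall",
    "average_precision",
    "map_50_95",
]


@dataclass(frozen=True)
class Detection:
    """A scored predicted box on one image."""

    box: PixelBox
    confidence: float
    image_id: Hashable = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence outside [0,1]: {self.confidence}")


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    # (prediction index, ground-truth index, IoU) for each matched pair
    pairs: Tuple[Tuple[int, int, float], ...] = ()


@dataclass(frozen=True)
class PRCurve:
    recalls: Tuple[float, ...]
    precisions: Tuple[float, ...]  # envelope-interpolated


@dataclass(frozen=True)
class MapConfig:
    """IoU thresholds 0.50, 0.55, ..., 0.95 over a single class."""

    iou_thresholds: Tuple[float, ...] = tuple(
        round(0.50 + 0.05 * j, 2) for j in range(10))
    n_classes: int = 1


class NoGroundTruthError(ValueError):
    """AP is undefined when the evaluation set contains no ground truth."""


def iou(a: PixelBox, b: PixelBox) -> float:
    """Intersection area over union area; 0 for disjoint boxes."""
    inter = a.intersect(b)
    if inter is None:
        return 0.0
    ia = inter.area
    return ia / (a.area + b.area - ia)


def _confidence_order(preds: Sequence[Detection]) -> List[int]:
    # stable: descending confidence, ties by input index
    return sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, i))


def match_detections(preds: Sequence[Detection],
                     gts: Sequence[PixelBox],
                     iou_threshold: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground truths."""
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    taken = [False] * len(gts)
    pairs: List[Tuple[int, int, float]] = []
    for pi in _confidence_order(preds):
        best_iou, best_gt = 0.0, -1
        for gi, gt in enumerate(gts):
            if taken[gi]:
                continue
            v = iou(preds[pi].box, gt)
            # ties on IoU resolved toward the lower ground-truth index
            if v > best_iou:
                best_iou, best_gt = v, gi
        if best_gt >= 0 and best_iou >= iou_threshold:
            taken[best_gt] = True
            pairs.append((pi, best_gt, best_iou))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(preds) - tp, fn=len(gts) - tp,
                       pairs=tuple(sorted(pairs)))


def precision(m: MatchResult) -> float:
    """TP / (TP + FP); defined as 1.0 when there are no predictions."""
    return m.tp / (m.tp + m.fp) if (m.tp + m.fp) else 1.0


def recall(m: MatchResult) -> float:
    """TP / (TP + FN); defined as 1.0 when there are no ground truths."""
    return m.tp / (m.tp + m.fn) if (m.tp + m.fn) else 1.0


def _tp_flags(preds: Sequence[Detection],
              gts: Mapping[Hashable, Sequence[PixelBox]],
              iou_threshold: float) -> Tuple[np.ndarray, int]:
    """Per-prediction TP flag in global confidence order, plus total gt count."""
    order = _confidence_order(preds)
    taken: Dict[Hashable, List[bool]] = {
        img: [False] * len(boxes) for img, boxes in gts.items()}
    flags = np.zeros(len(preds), dtype=bool)
    for rank, pi in enumerate(order):
        det = preds[pi]
        boxes = gts.get(det.image_id, ())
        used = taken.setdefault(det.image_id, [False] * len(boxes))
        best_iou, best_gt = 0.0, -1
        for gi, gt in enumerate(boxes):
            if used[gi]:
                continue
            v = iou(det.box, gt)
            if v > best_iou:
                best_iou, best_gt = v, gi
        if best_gt >= 0 and best_iou >= iou_threshold:
            used[best_gt] = True
            flags[rank] = True
    n_gt = sum(len(b) for b in gts.values())
    return flags, n_gt


def pr_curve(preds: Sequence[Detection],
             gts: Mapping[Hashable, Sequence[PixelBox]],
             iou_threshold: float = 0.5) -> PRCurve:
    """Envelope-interpolated precision at each observed recall level."""
    flags, n_gt = _tp_flags(preds, gts, iou_threshold)
    if n_gt == 0:
        raise NoGroundTruthError("no ground-truth objects in the evaluation set")
    if len(flags) == 0:
        return PRCurve((), ())
    tp_cum = np.cumsum(flags)
    prec = tp_cum / np.arange(1, len(flags) + 1)
    rec = tp_cum / n_gt
    # precision envelope: max precision at any recall >= r
    env = np.maximum.accumulate(prec[::-1])[::-1]
    return PRCurve(tuple(rec), tuple(env))


def average_precision(preds: Sequence[Detection],
                      gts: Mapping[Hashable, Sequence[PixelBox]],
                      iou_threshold: float = 0.5) -> float:
    """Sum of interpolated precision times recall increment (all-point AP)."""
    curve = pr_curve(preds, gts, iou_threshold)
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(curve.recalls, curve.precisions):
        ap += p * (r - prev_r)
        prev_r = r
    return ap


def map_50_95(preds: Sequence[Detection],
              gts: Mapping[Hashable, Sequence[PixelBox]],
              config: MapConfig = MapConfig()) -> float:
    """Mean AP over the ten IoU thresholds (single class)."""
    aps = [average_precision(preds, gts, t) for t in config.iou_thresholds]
    return float(np.mean(aps))
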