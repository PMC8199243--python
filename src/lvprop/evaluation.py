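"""Detection metrics: precision / recall / F1, average precision, mAP.

A detection counts as correct when its confidence exceeds the gate (0.7 by
default) and its IOU with an unmatched ground-truth box reaches the IOU
threshold; matching is greedy in descending score with each ground truth
used at most once.  P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).
AP integrates the precision-recall curve as the step sum
``sum_k (R_k - R_{k-1}) P_k`` (the non-interpolated convention); the
monotone-envelope variant is available via ``interpolated=True``.  mAP is
the unweighted mean of per-group (per-individual) APs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anchors import iou

__all__ = [
    "DetectionBox",
    "MatchTally",
    "EvalResult",
    "match",
    "precision",
    "recall",
    "f1",
    "average_precision",
    "map_over_groups",
    "evaluate",
]


@dataclass(frozen=True)
class DetectionBox:
    """A scored detection box (x1, y1, x2, y2 half-open)."""

    x1: float
    y1: float
    x2: float
    y2: float
    score: float = 1.0
    image_id: int = 0

    @property
    def box(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)


@dataclass
class MatchTally:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0
    iou_threshold: float = 0.5
    confidence_threshold: float = 0.7


@dataclass
class EvalResult:
    precision: float
    recall: float
    f1: float
    ap_by_threshold: dict[float, float] = field(default_factory=dict)
    map50: float | None = None


def _greedy_match(
    det_boxes: list, det_scores: np.ndarray, gt_boxes: list, thr: float
) -> list[bool]:
    """True/False TP flag per detection, in descending-score order."""
    order = np.argsort(-np.asarray(det_scores), kind="stable")
    matched = [False] * len(gt_boxes)
    flags_ordered = []
    for idx in order:
        best, best_iou = -1, 0.0
        for g, gb in enumerate(gt_boxes):
            if matched[g]:
                continue
            v = iou(det_boxes[idx], gb)
            if v > best_iou:
                best, best_iou = g, v
        if best >= 0 and best_iou >= thr:
            matched[best] = True
            flags_ordered.append(True)
        else:
            flags_ordered.append(False)
    return flags_ordered


def match(
    detections: list[DetectionBox],
    gt_boxes: list,
    iou_threshold: float = 0.5,
    confidence_threshold: float = 0.7,
) -> MatchTally:
    """Tally TP/FP/FN for one image's detections against ground truth.

    Detections below the confidence gate are dropped before matching.
    ``TN`` stays 0: background has no box-level realization.
    """
    kept = [d for d in detections if d.score > confidence_threshold]
    flags = _greedy_match(
        [d.box for d in kept], np.array([d.score for d in kept]), list(gt_boxes),
        iou_threshold,
    )
    tp = sum(flags)
    return MatchTally(
        TP=tp,
        FP=len(kept) - tp,
        FN=len(gt_boxes) - tp,
        iou_threshold=iou_threshold,
        confidence_threshold=confidence_threshold,
    )


def precision(t: MatchTally) -> float:
    return t.TP / (t.TP + t.FP) if (t.TP + t.FP) else 0.0


def recall(t: MatchTally) -> float:
    return t.TP / (t.TP + t.FN) if (t.TP + t.FN) else 0.0


def f1(t: MatchTally) -> float:
    p, r = precision(t), recall(t)
    return 2 * p * r / (p + r) if (p + r) else 0.0


def average_precision(
    detections: list[DetectionBox],
    gt_by_image: dict[int, list],
    iou_threshold: float = 0.5,
    confidence_threshold: float | None = None,
    interpolated: bool = False,
) -> float:
    """Average precision over a set of images at one IOU threshold.

    Detections are ranked by score across images; per image, greedy
    matching marks each as TP or FP.  The default integration rule is the
    step sum ``sum_k (R_k - R_{k-1}) P_k``; ``interpolated=True`` uses the
    monotone precision envelope instead.  The confidence gate is off by
    default (pass a threshold to pre-filter detections).
    """
    n_gt = sum(len(v) for v in gt_by_image.values())
    if n_gt == 0:
        raise ValueError("average precision is undefined with zero ground truth")
    if confidence_threshold is not None:
        detections = [d for d in detections if d.score > confidence_threshold]
    if not detections:
        return 0.0
    order = np.argsort(-np.array([d.score for d in detections]), kind="stable")
    matched: dict[int, list[bool]] = {
        k: [False] * len(v) for k, v in gt_by_image.items()
    }
    tp_flags = []
    for idx in order:
        d = detections[idx]
        gts = gt_by_image.get(d.image_id, [])
        best, best_iou = -1, 0.0
        for g, gb in enumerate(gts):
            if matched[d.image_id][g]:
                continue
            v = iou(d.box, gb)
            if v > best_iou:
                best, best_iou = g, v
        if best >= 0 and best_iou >= iou_threshold:
            matched[d.image_id][best] = True
            tp_flags.append(1.0)
        else:
            tp_flags.append(0.0)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(1.0 - np.array(tp_flags))
    prec = tp_cum / (tp_cum + fp_cum)
    rec = tp_cum / n_gt
    if interpolated:
        env = np.maximum.accumulate(prec[::-1])[::-1]
        r_prev = np.concatenate([[0.0], rec[:-1]])
        return float(np.sum((rec - r_prev) * env))
    r_prev = np.concatenate([[0.0], rec[:-1]])
    return float(np.sum((rec - r_prev) * prec))


def map_over_groups(ap_values) -> float:
    """Unweighted mean AP over groups (individuals)."""
    ap_values = list(ap_values)
    if not ap_values:
        raise ValueError("need at least one group")
    return float(np.mean(ap_values))


def evaluate(
    detections: list[DetectionBox],
    gt_by_image: dict[int, list],
    iou_threshold: float = 0.5,
    confidence_threshold: float = 0.7,
    ap_thresholds: tuple[float, ...] = (0.5, 0.75),
) -> EvalResult:
    """P/R/F1 at the confidence gate plus AP at the requested IOU levels."""
    tally = MatchTally(iou_threshold=iou_threshold,
                       confidence_threshold=confidence_threshold)
    for img_id, gts in gt_by_image.items():
        dets = [d for d in detections if d.image_id == img_id]
        t = match(dets, gts, iou_threshold, confidence_threshold)
        tally.TP += t.TP
        tally.FP += t.FP
        tally.FN += t.FN
    aps = {
        thr: average_precision(detections, gt_by_image, thr)
        for thr in ap_thresholds
    }
    return EvalResult(
        precision=precision(tally),
        recall=recall(tally),
        f1=f1(tally),
        ap_by_threshold=aps,
    )
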