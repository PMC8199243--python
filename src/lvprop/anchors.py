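"""Saliency anchors, the 9 scale-adaptive anchors, grid anchors and IOU labeling.

The saliency anchor is the tight bounding box of a selected LV candidate
region.  From it, 9 concentric "scale-adaptive" anchors are derived: three
basic boxes (the saliency anchor itself plus two squares — from the long and
short side if it is a rectangle, from the diagonal and semi-diagonal if it
is a square), each additionally scaled by the factors ``s1`` and ``s2``.
Their centers map onto the stride-16 feature grid of a region-proposal
network, replacing the generic grid anchors at those cells; positive /
negative / ignored samples are partitioned by IOU thresholds per stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Anchor",
    "AnchorConfig",
    "saliency_anchor",
    "scale_adaptive_anchors",
    "perturb_anchors",
    "map_to_feature_grid",
    "grid_anchors",
    "iou",
    "label_samples",
    "nms",
]


@dataclass(frozen=True)
class Anchor:
    """A box given by center (cx, cy), size (w, h) and an origin tag."""

    cx: float
    cy: float
    w: float
    h: float
    tag: str = "basic"

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError("anchor width/height must be positive")

    @property
    def box(self) -> tuple[float, float, float, float]:
        """Half-open (x1, y1, x2, y2)."""
        return (
            self.cx - self.w / 2,
            self.cy - self.h / 2,
            self.cx + self.w / 2,
            self.cy + self.h / 2,
        )

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass
class AnchorConfig:
    """Thresholds and scale factors of the anchor machinery.

    ``s1``/``s2`` default to the tracker-path factors (1.1 / 1.2); the
    dictionary path uses 0.8 / 0.9.  IOU bands follow the two-stage
    convention: RPN positives above 0.7, negatives below 0.3; proposal-layer
    positives above 0.5, negatives in (0.1, 0.5).
    """

    s1: float = 1.1
    s2: float = 1.2
    stride: int = 16
    grid_sizes: tuple[int, ...] = (64, 128, 256)
    grid_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    rpn_pos_iou: float = 0.7
    rpn_neg_iou: float = 0.3
    prop_pos_iou: float = 0.5
    prop_neg_band: tuple[float, float] = (0.1, 0.5)
    nms_iou: float = 0.7
    confidence: float = 0.7

    def __post_init__(self):
        if self.s1 <= 0 or self.s2 <= 0:
            raise ValueError("scale factors must be positive")
        for t in (self.rpn_pos_iou, self.rpn_neg_iou, self.prop_pos_iou,
                  *self.prop_neg_band, self.nms_iou):
            if not 0.0 <= t <= 1.0:
                raise ValueError("IOU thresholds must lie in [0, 1]")


DICT_PATH_SCALES = (0.8, 0.9)
TRACK_PATH_SCALES = (1.1, 1.2)


def saliency_anchor(region) -> Anchor:
    """Tight bounding box of a candidate region, tagged ``saliency``."""
    if region.area == 0:
        raise ValueError("empty candidate region")
    x1, y1, x2, y2 = region.bounding_box
    return Anchor(
        cx=(x1 + x2) / 2.0,
        cy=(y1 + y2) / 2.0,
        w=float(x2 - x1),
        h=float(y2 - y1),
        tag="saliency",
    )


def scale_adaptive_anchors(
    sal: Anchor, s1: float = 1.1, s2: float = 1.2
) -> list[Anchor]:
    """The 9 concentric scale-adaptive anchors of a saliency anchor.

    Three basic boxes are built first: the saliency anchor itself plus two
    squares — with the long and short side for a rectangle, or the diagonal
    and semi-diagonal for a square.  Each basic box scaled by ``s1`` and by
    ``s2`` contributes six more, for 9 anchors sharing the saliency center.
    """
    w, h = sal.w, sal.h
    if abs(w - h) < 1e-9:  # square (1x1 degenerate included)
        diag = w * np.sqrt(2.0)
        basics = [(w, h), (diag, diag), (diag / 2.0, diag / 2.0)]
    else:
        long_s, short_s = max(w, h), min(w, h)
        basics = [(w, h), (long_s, long_s), (short_s, short_s)]
    out = [Anchor(sal.cx, sal.cy, bw, bh, tag="basic") for bw, bh in basics]
    for s, tag in ((s1, "scaled-s1"), (s2, "scaled-s2")):
        out += [
            Anchor(sal.cx, sal.cy, bw * s, bh * s, tag=tag) for bw, bh in basics
        ]
    return out


def perturb_anchors(
    anchor_set: list[Anchor],
    sal: Anchor,
    n_draws: int,
    seed: int = 0,
) -> list[Anchor]:
    """Augmentation replicas with centers resampled inside the saliency box.

    Each of the ``n_draws`` replicas redraws every anchor's center uniformly
    inside the saliency anchor (sizes unchanged), diversifying the positive
    samples around the LV.  Deterministic for a fixed seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    x1, y1, x2, y2 = sal.box
    out = []
    for _ in range(n_draws):
        for a in anchor_set:
            out.append(
                Anchor(
                    cx=float(rng.uniform(x1, x2)),
                    cy=float(rng.uniform(y1, y2)),
                    w=a.w,
                    h=a.h,
                    tag="perturbed",
                )
            )
    return out


def map_to_feature_grid(
    centers: np.ndarray, stride: int = 16
) -> np.ndarray:
    """Map image-space centers (x, y) to feature-grid cells by floor division."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if np.any(centers < 0):
        raise ValueError("negative center coordinates cannot be mapped")
    return np.floor(centers / stride).astype(int)


def grid_anchors(
    image_shape: tuple[int, int],
    sizes: tuple[int, ...] = (64, 128, 256),
    ratios: tuple[float, ...] = (0.5, 1.0, 2.0),
    stride: int = 16,
) -> list[Anchor]:
    """Baseline RPN grid anchors: 3 sizes x 3 ratios per stride-16 cell.

    Ratio ``r`` preserves area: ``w = s*sqrt(r)``, ``h = s/sqrt(r)``.
    Centers sit at cell centers.
    """
    h, w = image_shape
    out = []
    for gy in range(h // stride):
        for gx in range(w // stride):
            cx, cy = (gx + 0.5) * stride, (gy + 0.5) * stride
            for s in sizes:
                for r in ratios:
                    out.append(
                        Anchor(cx, cy, s * np.sqrt(r), s / np.sqrt(r),
                               tag="grid")
                    )
    return out


def iou(a, b) -> float:
    """Intersection over union of two half-open boxes (x1, y1, x2, y2)."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    area_a = max(ax2 - ax1, 0.0) * max(ay2 - ay1, 0.0)
    area_b = max(bx2 - bx1, 0.0) * max(by2 - by1, 0.0)
    if area_a == 0.0 or area_b == 0.0:
        return 0.0
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    boxes_a = np.atleast_2d(np.asarray(boxes_a, dtype=float))
    boxes_b = np.atleast_2d(np.asarray(boxes_b, dtype=float))
    return np.array([[iou(a, b) for b in boxes_b] for a in boxes_a])


def label_samples(
    anchor_boxes: np.ndarray,
    gt_boxes: np.ndarray,
    stage: str,
    config: AnchorConfig | None = None,
    force_gt_argmax: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition anchors into positive / negative / ignore by max IOU.

    Stage ``"rpn"`` uses strict bands IOU > 0.7 positive, IOU < 0.3
    negative; stage ``"proposal"`` uses IOU > 0.5 positive and
    0.1 < IOU < 0.5 negative.  Everything else is ignored.  With
    ``force_gt_argmax`` each ground-truth box's single highest-IOU anchor is
    additionally positive, so no ground truth goes unrepresented.

    Returns ``(labels, max_ious)`` with labels in
    ``{"positive", "negative", "ignore"}``.
    """
    if config is None:
        config = AnchorConfig()
    gt_boxes = np.atleast_2d(np.asarray(gt_boxes, dtype=float))
    if gt_boxes.shape[0] < 1:
        raise ValueError("need at least one ground-truth box")
    M = iou_matrix(anchor_boxes, gt_boxes)
    max_iou = M.max(axis=1)
    labels = np.full(max_iou.shape[0], "ignore", dtype=object)
    if stage == "rpn":
        labels[max_iou > config.rpn_pos_iou] = "positive"
        labels[max_iou < config.rpn_neg_iou] = "negative"
    elif stage == "proposal":
        lo, hi = config.prop_neg_band
        labels[(max_iou > lo) & (max_iou < hi)] = "negative"
        labels[max_iou > config.prop_pos_iou] = "positive"
    else:
        raise ValueError(f"unknown stage {stage!r}")
    if force_gt_argmax:
        for g in range(gt_boxes.shape[0]):
            labels[int(np.argmax(M[:, g]))] = "positive"
    return labels.astype(str), max_iou


def nms(
    boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.7
) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices by score order.

    A box is suppressed when its IOU with an already-kept box exceeds the
    threshold (strictly).
    """
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    kept: list[int] = []
    for idx in order:
        if all(iou(boxes[idx], boxes[k]) <= iou_threshold for k in kept):
            kept.append(int(idx))
    return kept
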