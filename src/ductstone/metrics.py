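"""Classification and weak-localization metrics.

Classification uses a 0.5 decision threshold on the stone probability.
Localization reports (i) mIoU averaged over *all* stone-containing images,
an image with no predicted box contributing zero, and (ii) average
precision at a single IoU match threshold (default 0.5) with all-point
interpolation, one detection per image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io import BoundingBox, DetectionRecord

__all__ = [
    "MetricsReport",
    "classification_metrics",
    "iou",
    "mean_iou",
    "average_precision",
    "random_box_miou",
]


@dataclass
class MetricsReport:
    n_images: int
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    miou: float = float("nan")
    ap: float = float("nan")
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "miou": self.miou,
            "ap": self.ap,
            **self.extras,
        }


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def classification_metrics(
    records: Sequence[DetectionRecord],
    labels: Mapping[str, int],
    threshold: float = 0.5,
) -> MetricsReport:
    """Confusion counts and derived rates at the given score threshold."""
    by_id = {r.image_id: r for r in records}
    missing = sorted(set(labels) - set(by_id))
    if missing:
        raise ValidationError(f"no detection record for labelled images: {missing}")
    tp = fp = tn = fn = 0
    for image_id, y in labels.items():
        pred = 1 if by_id[image_id].score >= threshold else 0
        if y == 1:
            tp += pred
            fn += 1 - pred
        else:
            fp += pred
            tn += 1 - pred
    n = len(labels)
    return MetricsReport(
        n_images=n,
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=_ratio(tp + tn, n, "accuracy"),
        sensitivity=_ratio(tp, tp + fn, "sensitivity"),
        specificity=_ratio(tn, tn + fp, "specificity"),
        f1=_ratio(2 * tp, 2 * tp + fp + fn, "f1"),
    )


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open pixel boxes."""
    ix = max(0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def mean_iou(
    records: Sequence[DetectionRecord],
    gt_boxes: Mapping[str, BoundingBox],
) -> float:
    """Mean IoU over every ground-truth (stone) image; misses score zero."""
    if not gt_boxes:
        return float("nan")
    by_id = {r.image_id: r for r in records}
    total = 0.0
    for image_id, gt in gt_boxes.items():
        rec = by_id.get(image_id)
        if rec is None:
            raise ValidationError(f"no detection record for positive image {image_id!r}")
        if rec.box is not None:
            total += iou(rec.box, gt)
    return total / len(gt_boxes)


def average_precision(
    records: Sequence[DetectionRecord],
    gt_boxes: Mapping[str, BoundingBox],
    iou_threshold: float = 0.5,
) -> float:
    """All-point-interpolated AP with one detection per image.

    A detection matches iff its image has a ground-truth box and the IoU
    meets the threshold; detections are ranked by classifier score.
    """
    n_pos = len(gt_boxes)
    if n_pos == 0:
        return float("nan")
    dets = [r for r in records if r.box is not None]
    dets.sort(key=lambda r: (-r.score, r.image_id))
    hits = np.array(
        [r.image_id in gt_boxes and iou(r.box, gt_boxes[r.image_id]) >= iou_threshold
         for r in dets],
        dtype=float,
    )
    if hits.size == 0:
        return 0.0
    tp = np.cumsum(hits)
    fp = np.cumsum(1.0 - hits)
    recall = tp / n_pos
    precision = tp / (tp + fp)
    # precision envelope (monotone non-increasing from the right)
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def random_box_miou(
    records: Sequence[DetectionRecord],
    gt_boxes: Mapping[str, BoundingBox],
    image_shape: tuple[int, int],
    rng: np.random.Generator,
    n_trials: int = 20,
) -> float:
    """Chance baseline: re-place each predicted box uniformly at random
    (same size) and recompute mIoU; averaged over trials."""
    h, w = image_shape
    by_id = {r.image_id: r for r in records}
    totals = np.zeros(n_trials)
    for t in range(n_trials):
        total = 0.0
        for image_id, gt in gt_boxes.items():
            rec = by_id.get(image_id)
            if rec is None or rec.box is None:
                continue
            bw = min(rec.box.width, w)
            bh = min(rec.box.height, h)
            x0 = int(rng.integers(0, w - bw + 1))
            y0 = int(rng.integers(0, h - bh + 1))
            total += iou(BoundingBox(x0, y0, x0 + bw, y0 + bh), gt)
        totals[t] = total / len(gt_boxes)
    return float(totals.mean())
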