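"""Reduction of per-image detections to a binary ripeness label.

An object detector emits bounding boxes with class and confidence. To obtain
an image-level label, boxes below a confidence threshold are discarded,
overlapping same-class boxes are merged by greedy non-maximum suppression,
and the image is labelled *ripe* if any ripe box survives, otherwise
*unripe* (which covers both "only unripe fruit" and "no fruit found").
Night samples have no image; they carry an unavailable Prediction and can be
counted either as missing or as misclassifications when projecting accuracy
to the full timeline.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import Detection, Prediction

__all__ = [
    "DEFAULT_CONF_THRESHOLD",
    "DEFAULT_IOU_THRESHOLD",
    "iou",
    "nms",
    "image_label",
    "project_accuracy",
]

DEFAULT_CONF_THRESHOLD = 0.8
DEFAULT_IOU_THRESHOLD = 0.5


def iou(a, b) -> float:
    """Intersection over union of two (x1, y1, x2, y2) boxes."""
    ax1, ay1, ax2, ay2 = a.box if isinstance(a, Detection) else a
    bx1, by1, bx2, by2 = b.box if isinstance(b, Detection) else b
    ix = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    iy = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = ix * iy
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


def nms(
    detections: Sequence[Detection], iou_threshold: float = DEFAULT_IOU_THRESHOLD
) -> list[Detection]:
    """Greedy per-class non-maximum suppression.

    Boxes are visited in descending confidence (ties broken by box
    coordinates for determinism); a box is kept unless it overlaps an
    already-kept box of the same class with IoU above the threshold.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must be in (0, 1)")
    ordered = sorted(
        detections, key=lambda d: (-d.conf, d.cls, d.x1, d.y1, d.x2, d.y2)
    )
    kept: list[Detection] = []
    for d in ordered:
        if all(
            k.cls != d.cls or iou(k, d) <= iou_threshold for k in kept
        ):
            kept.append(d)
    return kept


def image_label(
    detections: Sequence[Detection] | None,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
    sample_id: str = "",
    positive_class: str = "ripe",
    negative_class: str = "unripe",
) -> Prediction:
    """Collapse an image's detections to one binary Prediction.

    ``None`` detections mean no usable image (night): the returned Prediction
    has ``available=False``. Otherwise boxes below ``conf_threshold`` are
    dropped, NMS is applied, and any surviving positive-class box makes the
    image positive with confidence equal to the best surviving positive
    confidence. A negative image's confidence is
    ``max(1 - best filtered-out positive conf, best surviving negative conf)``
    (1.0 when no positive box was ever proposed) — high when nothing
    ripe-like was seen at any confidence.
    """
    if not 0.0 <= conf_threshold <= 1.0:
        raise ValueError("conf_threshold must be in [0, 1]")
    if detections is None:
        return Prediction(
            sample_id=sample_id,
            label=negative_class,
            confidence=0.0,
            modality="image",
            available=False,
        )
    surviving = nms(
        [d for d in detections if d.conf >= conf_threshold], iou_threshold
    )
    pos = [d for d in surviving if d.cls == positive_class]
    if pos:
        return Prediction(
            sample_id=sample_id,
            label=positive_class,
            confidence=max(d.conf for d in pos),
            modality="image",
        )
    pos_any = [d.conf for d in detections if d.cls == positive_class]
    neg_surv = [d.conf for d in surviving if d.cls == negative_class]
    conf = max(
        1.0 - (max(pos_any) if pos_any else 0.0),
        max(neg_surv, default=0.0),
    )
    return Prediction(
        sample_id=sample_id,
        label=negative_class,
        confidence=float(conf),
        modality="image",
    )


def project_accuracy(
    predictions: Sequence[Prediction],
    labels: Sequence[str],
    mode: str = "available_only",
) -> float:
    """Accuracy of an intermittently available modality.

    ``available_only`` scores only samples the modality saw;
    ``all_counting_missing_wrong`` projects to the full timeline, counting
    every unavailable sample as a misclassification.
    """
    if len(predictions) != len(labels):
        raise ValueError("prediction/label length mismatch")
    correct = sum(
        1
        for p, t in zip(predictions, labels)
        if p.available and p.label == str(t)
    )
    if mode == "available_only":
        n_avail = sum(p.available for p in predictions)
        return correct / n_avail if n_avail else 0.0
    if mode == "all_counting_missing_wrong":
        return correct / len(predictions) if predictions else 0.0
    raise ValueError(f"unknown mode {mode!r}")
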