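"""Precision-recall evaluation: greedy matching and average precision.

AP at an overlap threshold ``t`` pools detections from all images, ranks
them globally by confidence, and integrates the all-point interpolated
precision-recall curve (precision envelope), the modern single-class
convention.  ``AP_n`` denotes the threshold ``n/100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .head import BoundingBox, iou

__all__ = ["EvalResult", "match_detections", "average_precision", "evaluate_detections"]


@dataclass
class EvalResult:
    iou_threshold: float
    ap: float
    precision_curve: list[float]
    recall_curve: list[float]
    n_images: int
    n_gt_boxes: int


def match_detections(dets: list[BoundingBox], gts: list[BoundingBox],
                     iou_threshold: float) -> tuple[list[bool], list[bool], int]:
    """Greedy one-to-one matching in descending confidence order.

    Returns per-detection TP and FP flags (aligned with the confidence-
    sorted detections) and the count of unmatched ground truths.  A
    detection is a true positive iff its best-overlap unmatched ground
    truth reaches the threshold; each ground truth matches at most once.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    matched = [False] * len(gts)
    tp = [False] * len(dets)
    fp = [False] * len(dets)
    for rank, i in enumerate(order):
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(gts):
            if matched[j]:
                continue
            v = iou(dets[i], gt)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            tp[rank] = True
        else:
            fp[rank] = True
    fn = matched.count(False)
    return tp, fp, fn


def average_precision(matches: list[tuple[list[BoundingBox], list[bool]]],
                      n_gt_boxes: int, iou_threshold: float,
                      n_images: int | None = None) -> EvalResult:
    """Integrate a pooled precision-recall curve.

    ``matches`` holds, per image, the confidence-sorted detections and
    their TP flags from :func:`match_detections`.  Detections are then
    ranked globally by confidence (micro-averaging).  Zero ground-truth
    boxes make recall undefined and raise.
    """
    if n_gt_boxes <= 0:
        raise ValueError("average precision is undefined with zero ground-truth boxes")
    pooled: list[tuple[float, bool]] = []
    for dets, tp_flags in matches:
        pooled.extend((d.score, t) for d, t in zip(dets, tp_flags))
    pooled.sort(key=lambda p: -p[0])

    tp_cum = np.cumsum([t for _, t in pooled]) if pooled else np.array([])
    fp_cum = np.cumsum([not t for _, t in pooled]) if pooled else np.array([])
    if len(pooled) == 0:
        return EvalResult(iou_threshold, 0.0, [], [], n_images or len(matches), n_gt_boxes)
    precision = tp_cum / (tp_cum + fp_cum)
    recall = tp_cum / n_gt_boxes

    # all-point interpolation: precision envelope, integrate over recall steps
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for p, r in zip(envelope, recall):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return EvalResult(
        iou_threshold=float(iou_threshold),
        ap=float(ap),
        precision_curve=[float(v) for v in precision],
        recall_curve=[float(v) for v in recall],
        n_images=n_images if n_images is not None else len(matches),
        n_gt_boxes=n_gt_boxes,
    )


def evaluate_detections(per_image: list[tuple[list[BoundingBox], list[BoundingBox]]],
                        iou_threshold: float) -> EvalResult:
    """Convenience wrapper: ``(detections, ground_truths)`` pairs to an EvalResult."""
    matches = []
    n_gt = 0
    for dets, gts in per_image:
        dets_sorted = sorted(dets, key=lambda b: -b.score)
        tp, _fp, _fn = match_detections(dets_sorted, gts, iou_threshold)
        matches.append((dets_sorted, tp))
        n_gt += len(gts)
    return average_precision(matches, n_gt, iou_threshold, n_images=len(per_image))
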