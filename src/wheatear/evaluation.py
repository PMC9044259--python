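"""Detection evaluation: NMS, greedy matching, precision/recall and AP.

Matching follows the usual single-threshold protocol: predictions are
visited in descending confidence and each may claim the unmatched ground
truth with the highest IoU, provided that IoU reaches the threshold
(0.5 by default).  Precision = TP/(TP+FP), Recall = TP/(TP+FN), and AP is
the area under the precision envelope over recall — the all-point
interpolation of the integral definition AP = ∫ P(R) dR.  With a single
wheat-ear class, mAP equals AP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .boxes import Box, boxes_to_array, iou_matrix


@dataclass
class DetectionMetrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    precision: float = 0.0
    recall: float = 0.0
    ap: float = 0.0
    pr_curve: list = field(default_factory=list)   # ordered (recall, precision)

    @property
    def map50(self) -> float:
        """Single-class mAP at the matching threshold used (= AP)."""
        return self.ap

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"tp": self.tp, "fp": self.fp, "fn": self.fn,
                       "precision": self.precision, "recall": self.recall,
                       "ap": self.ap}, fh, indent=2)

    def pr_curve_to_csv(self, path):
        import pandas as pd
        pd.DataFrame(self.pr_curve, columns=["recall", "precision"]).to_csv(
            path, index=False)


def nms(boxes: list[Box], iou_threshold: float = 0.45) -> list[Box]:
    """Greedy non-maximum suppression, highest confidence first."""
    if not boxes:
        return []
    arr = boxes_to_array(boxes)
    conf = np.array([b.confidence if b.confidence is not None else 1.0
                     for b in boxes])
    order = np.argsort(-conf, kind="stable")
    keep: list[int] = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for idx in order:
        if suppressed[idx]:
            continue
        keep.append(idx)
        ious = iou_matrix(arr[idx:idx + 1], arr)[0]
        suppressed |= ious >= iou_threshold
        suppressed[idx] = True
    return [boxes[i] for i in keep]


def match_detections(preds: list[Box], gt: list[Box],
                     iou_threshold: float = 0.5):
    """Greedy one-to-one matching of predictions to ground truth.

    Returns (tp, fp, fn, flags) where ``flags[k]`` says whether the k-th
    prediction *in descending confidence order* is a true positive.
    Ties on IoU break toward the lower ground-truth index.
    """
    conf = np.array([b.confidence if b.confidence is not None else 1.0
                     for b in preds])
    order = np.argsort(-conf, kind="stable")
    flags = np.zeros(len(preds), dtype=bool)
    if len(gt) == 0 or len(preds) == 0:
        return 0, len(preds), len(gt), flags
    ious = iou_matrix(boxes_to_array([preds[i] for i in order]),
                      boxes_to_array(gt))
    taken = np.zeros(len(gt), dtype=bool)
    for k in range(len(order)):
        row = np.where(taken, -1.0, ious[k])
        best = int(row.argmax())   # argmax returns the first maximum: GT-index tie-break
        if row[best] >= iou_threshold:
            taken[best] = True
            flags[k] = True
    tp = int(flags.sum())
    return tp, len(preds) - tp, int((~taken).sum()), flags


def average_precision(preds_per_image: list[list[Box]],
                      gt_per_image: list[list[Box]],
                      iou_threshold: float = 0.5) -> DetectionMetrics:
    """AP over a dataset by sweeping the confidence ranking.

    Predictions from all images are pooled and ranked by confidence;
    matching is per-image.  The PR curve is integrated under its upper
    envelope (all-point interpolation).
    """
    n_gt = sum(len(g) for g in gt_per_image)
    if n_gt == 0:
        raise ValueError("AP is undefined on a dataset with no ground truth")
    records = []   # (confidence, image index, is-tp flag placeholder)
    tp_flags_per_image = []
    for img, (preds, gts) in enumerate(zip(preds_per_image, gt_per_image)):
        _, _, _, flags = match_detections(preds, gts, iou_threshold)
        conf = np.array([b.confidence if b.confidence is not None else 1.0
                         for b in preds])
        order = np.argsort(-conf, kind="stable")
        for rank, k in enumerate(order):
            records.append((float(conf[k]), img, rank, bool(flags[rank])))
    # global ranking; stable on (image, per-image rank) for determinism
    records.sort(key=lambda r: (-r[0], r[1], r[2]))
    tp_cum = fp_cum = 0
    curve = []
    for conf, _, _, is_tp in records:
        if is_tp:
            tp_cum += 1
        else:
            fp_cum += 1
        curve.append((tp_cum / n_gt, tp_cum / (tp_cum + fp_cum)))
    ap = _envelope_area(curve)
    tp, fp = tp_cum, fp_cum
    fn = n_gt - tp
    return DetectionMetrics(
        tp=tp, fp=fp, fn=fn,
        precision=tp / (tp + fp) if tp + fp else 0.0,
        recall=tp / n_gt,
        ap=ap, pr_curve=curve)


def _envelope_area(curve) -> float:
    """Area under the precision upper-envelope of an ordered PR sweep."""
    if not curve:
        return 0.0
    recalls = np.array([r for r, _ in curve])
    precisions = np.array([p for _, p in curve])
    # envelope: at each recall, the best precision achievable at >= recall
    env = np.maximum.accumulate(precisions[::-1])[::-1]
    r_prev = 0.0
    area = 0.0
    for r, p in zip(recalls, env):
        if r > r_prev:
            area += (r - r_prev) * p
            r_prev = r
    return float(area)


def evaluate(model, dataset, conf_threshold: float = 0.25,
             nms_threshold: float = 0.45,
             iou_threshold: float = 0.5) -> DetectionMetrics:
    """Run inference over (image, gt-boxes) pairs and aggregate metrics.

    ``dataset`` yields (image array HxWx3 uint8 or float, list of Box).
    Throughput (images/s) is logged as a convenience; it is hardware-bound
    and intentionally not part of any returned metric.
    """
    import logging
    import time
    t0 = time.perf_counter()
    preds_all, gts_all = [], []
    count = 0
    for image, gts in dataset:
        count += 1
        img = np.asarray(image)
        if img.dtype == np.uint8:
            img = img.astype(np.float32) / 255.0
        x = img.transpose(2, 0, 1)[None]
        boxes = model.predict(x, conf_threshold=conf_threshold,
                              nms_threshold=nms_threshold)[0]
        preds_all.append(boxes)
        gts_all.append(list(gts))
    if count == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    elapsed = time.perf_counter() - t0
    logging.getLogger("wheatear").info(
        "evaluated %d images in %.2fs (%.2f images/s)",
        count, elapsed, count / max(elapsed, 1e-9))
    return average_precision(preds_all, gts_all, iou_threshold)
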