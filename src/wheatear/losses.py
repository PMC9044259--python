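"""Box-overlap losses (IoU / GIoU / CIoU), target assignment and the
composite detection training loss.

The scalar functions operate on :class:`~wheatear.boxes.Box` pairs (or any
4-sequence) and are the reference geometry; the ``*_t`` variants operate on
autodiff tensors of box components and drive training.

CIoU extends IoU with a normalised centre-distance term and an
aspect-ratio penalty:

    CIOU_LOSS = 1 - IoU + rho^2 / c^2 + alpha * v

where rho is the distance between the two box centres, c the diagonal of
the smallest enclosing rectangle, v = (4/pi^2) (arctan(wg/hg) -
arctan(w/h))^2 and alpha = v / ((1 - IoU) + v).  alpha is treated as a
constant with respect to gradients within a step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .boxes import Box, as_box, boxes_to_array
from .neck import ANCHORS_PER_LEVEL, STRIDES, AnchorSet, _wh_iou


# ---------------------------------------------------------------------------
# scalar box geometry
# ---------------------------------------------------------------------------

def iou(a, b) -> float:
    """Intersection over union of two boxes; symmetric, in [0, 1]."""
    a, b = as_box(a), as_box(b)
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def iou_loss(a, b) -> float:
    """1 - IoU; saturates at 1 for disjoint boxes."""
    return 1.0 - iou(a, b)


def _enclosing(a: Box, b: Box) -> tuple[float, float, float, float]:
    return (min(a.x1, b.x1), min(a.y1, b.y1),
            max(a.x2, b.x2), max(a.y2, b.y2))


def giou_loss(a, b) -> float:
    """1 - IoU + |C - A∪B| / C with C the smallest enclosing rectangle."""
    a, b = as_box(a), as_box(b)
    ex1, ey1, ex2, ey2 = _enclosing(a, b)
    c_area = (ex2 - ex1) * (ey2 - ey1)
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return 1.0 - inter / union + (c_area - union) / c_area


def ciou_loss(a, b) -> float:
    """Complete-IoU loss: IoU, centre distance and aspect-ratio penalty.

    ``a`` is the prediction, ``b`` the ground truth (the roles only matter
    for which aspect ratio anchors the penalty).
    """
    a, b = as_box(a), as_box(b)
    iou_v = iou(a, b)
    ex1, ey1, ex2, ey2 = _enclosing(a, b)
    diag2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2
    (acx, acy), (bcx, bcy) = a.center, b.center
    rho2 = (acx - bcx) ** 2 + (acy - bcy) ** 2
    v = (4.0 / math.pi ** 2) * (math.atan(b.width / b.height)
                                - math.atan(a.width / a.height)) ** 2
    alpha = v / ((1.0 - iou_v) + v) if v > 0 else 0.0
    return 1.0 - (iou_v - rho2 / diag2 - alpha * v)


# ---------------------------------------------------------------------------
# differentiable CIoU on tensor box components
# ---------------------------------------------------------------------------

def ciou_loss_t(px1, py1, px2, py2, gt: np.ndarray):
    """Mean CIoU loss between predicted corner tensors and constant GT.

    ``px1..py2`` are (P,) autodiff tensors; ``gt`` is a constant (P, 4)
    corner array.  alpha is computed from current values and held fixed
    for the backward pass.
    """
    gx1, gy1, gx2, gy2 = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]
    eps = 1e-9
    pw = ad.maximum(px2 - px1, eps)
    ph = ad.maximum(py2 - py1, eps)
    gw, gh = gx2 - gx1, gy2 - gy1
    inter_w = ad.maximum(ad.minimum(px2, gx2) - ad.maximum(px1, gx1), 0.0)
    inter_h = ad.maximum(ad.minimum(py2, gy2) - ad.maximum(py1, gy1), 0.0)
    inter = inter_w * inter_h
    union = pw * ph + gw * gh - inter
    iou_t = inter / (union + eps)
    ex1 = ad.minimum(px1, gx1)
    ey1 = ad.minimum(py1, gy1)
    ex2 = ad.maximum(px2, gx2)
    ey2 = ad.maximum(py2, gy2)
    diag2 = (ex2 - ex1) ** 2.0 + (ey2 - ey1) ** 2.0 + eps
    rho2 = (((px1 + px2) - (gx1 + gx2)) * 0.5) ** 2.0 \
        + (((py1 + py2) - (gy1 + gy2)) * 0.5) ** 2.0
    v = (4.0 / math.pi ** 2) * (ad.arctan(gw / gh) - ad.arctan(pw / ph)) ** 2.0
    # alpha: stop-gradient constant, recomputed each step
    alpha = v.data / ((1.0 - iou_t.data) + v.data + eps)
    loss = 1.0 - iou_t + rho2 / diag2 + ad.mul(v, alpha)
    return loss.mean()


# ---------------------------------------------------------------------------
# target assignment
# ---------------------------------------------------------------------------

@dataclass
class LossWeights:
    box: float = 5.0
    objectness: float = 1.0
    class_: float = 1.0
    band_box: float = 1.0   # box pull on ignore-band cells (duplicates)

    def __post_init__(self):
        if min(self.box, self.objectness, self.class_, self.band_box) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LevelTargets:
    """Assignment result for one pyramid level of one image.

    Besides the positive set, an *ignore band* lists the anchor-cells
    whose grid centre falls inside some ground-truth box without being
    the assigned cell.  Band cells are ambiguous: they look at the object
    but cannot represent its centre under the in-cell sigmoid decode.
    The training loss leaves their objectness alone and regresses their
    box towards the containing object, so that whatever fires there is
    removed by NMS as a duplicate instead of surviving as a false
    positive.
    """

    obj: np.ndarray          # (A, H, W) 0/1 objectness target
    pos_anchor: np.ndarray   # (P,) anchor index within level
    pos_i: np.ndarray        # (P,) grid row
    pos_j: np.ndarray        # (P,) grid column
    pos_gt: np.ndarray       # (P, 4) matched ground-truth corners
    band_anchor: np.ndarray = None   # (B,) ignore-band anchor index
    band_i: np.ndarray = None        # (B,)
    band_j: np.ndarray = None        # (B,)
    band_gt: np.ndarray = None       # (B, 4) containing ground truth


def assign_targets(gt_boxes, anchors: AnchorSet, grid_shapes,
                   iou_threshold: float = 0.5) -> list[LevelTargets]:
    """YOLO-style anchor assignment for one image.

    Each ground-truth box goes to its best-IoU anchor (by centred
    width/height IoU over all 9 priors) at the grid cell containing its
    centre on that anchor's level; any other anchor with IoU >= threshold
    is additionally marked positive.  First-come-first-served on cell
    collisions, in ground-truth order.
    """
    gt = boxes_to_array(gt_boxes)
    levels = [LevelTargets(obj=np.zeros((ANCHORS_PER_LEVEL, h, w)),
                           pos_anchor=None, pos_i=None, pos_j=None, pos_gt=None)
              for (h, w) in grid_shapes]
    acc = [([], [], [], []) for _ in grid_shapes]
    if len(gt):
        wh = np.stack([gt[:, 2] - gt[:, 0], gt[:, 3] - gt[:, 1]], axis=1)
        ious = _wh_iou(wh, anchors.sizes)          # (M, 9)
        for m in range(len(gt)):
            chosen = set(np.flatnonzero(ious[m] >= iou_threshold))
            chosen.add(int(ious[m].argmax()))
            cx = (gt[m, 0] + gt[m, 2]) / 2
            cy = (gt[m, 1] + gt[m, 3]) / 2
            for flat in sorted(chosen):
                lvl, a = divmod(flat, ANCHORS_PER_LEVEL)
                h, w = grid_shapes[lvl]
                j = int(cx // STRIDES[lvl])
                i = int(cy // STRIDES[lvl])
                if not (0 <= i < h and 0 <= j < w):
                    continue
                if levels[lvl].obj[a, i, j]:
                    continue
                levels[lvl].obj[a, i, j] = 1.0
                aa, ii, jj, gg = acc[lvl]
                aa.append(a)
                ii.append(i)
                jj.append(j)
                gg.append(gt[m])
    out = []
    for lvl, (lt, (aa, ii, jj, gg)) in enumerate(zip(levels, acc)):
        # ignore band: anchor-cells whose centre sits inside a GT box but
        # which were not assigned (first GT claims a contested cell)
        ba, bi, bj, bg = [], [], [], []
        if len(gt):
            h, w = grid_shapes[lvl]
            stride = STRIDES[lvl]
            claimed = {}
            for m in range(len(gt)):
                j0 = max(int(gt[m, 0] // stride), 0)
                j1 = min(int(gt[m, 2] // stride) + 1, w)
                i0 = max(int(gt[m, 1] // stride), 0)
                i1 = min(int(gt[m, 3] // stride) + 1, h)
                for i in range(i0, i1):
                    cy = (i + 0.5) * stride
                    if not gt[m, 1] <= cy < gt[m, 3]:
                        continue
                    for j in range(j0, j1):
                        cx = (j + 0.5) * stride
                        if not gt[m, 0] <= cx < gt[m, 2]:
                            continue
                        # band target: the GT box translated to this
                        # cell's centre — exactly representable by the
                        # in-cell decode, and a clean NMS duplicate
                        gw = gt[m, 2] - gt[m, 0]
                        gh = gt[m, 3] - gt[m, 1]
                        shifted = np.array([cx - gw / 2, cy - gh / 2,
                                            cx + gw / 2, cy + gh / 2])
                        for a in range(ANCHORS_PER_LEVEL):
                            if lt.obj[a, i, j] or (a, i, j) in claimed:
                                continue
                            claimed[(a, i, j)] = True
                            ba.append(a)
                            bi.append(i)
                            bj.append(j)
                            bg.append(shifted)
        out.append(LevelTargets(
            obj=lt.obj,
            pos_anchor=np.asarray(aa, dtype=np.intp),
            pos_i=np.asarray(ii, dtype=np.intp),
            pos_j=np.asarray(jj, dtype=np.intp),
            pos_gt=(np.stack(gg) if gg else np.zeros((0, 4))),
            band_anchor=np.asarray(ba, dtype=np.intp),
            band_i=np.asarray(bi, dtype=np.intp),
            band_j=np.asarray(bj, dtype=np.intp),
            band_gt=(np.stack(bg) if bg else np.zeros((0, 4)))))
    return out


# ---------------------------------------------------------------------------
# composite training loss
# ---------------------------------------------------------------------------

def _gather(targets_per_image, lvl, prefix):
    """Batch-concatenate (image, anchor, i, j, gt) index arrays."""
    bs, as_, is_, js, gts = [], [], [], [], []
    for b, per_level in enumerate(targets_per_image):
        lt = per_level[lvl]
        aa = getattr(lt, prefix + "_anchor")
        if aa is not None and len(aa):
            bs.append(np.full(len(aa), b, dtype=np.intp))
            as_.append(aa)
            is_.append(getattr(lt, prefix + "_i"))
            js.append(getattr(lt, prefix + "_j"))
            gts.append(getattr(lt, prefix + "_gt"))
    if not bs:
        return None
    return (np.concatenate(bs), np.concatenate(as_), np.concatenate(is_),
            np.concatenate(js), np.concatenate(gts))


def _decoded_ciou(pred, idx, anchors_lvl, stride, gt):
    """Differentiable decode at the indexed cells + CIoU against gt."""
    bi, ai, ii, jj = idx
    sel = pred[(bi, ai, ii, jj)]            # (K, 6) gathered vectors
    aw = anchors_lvl[ai, 0]
    ah = anchors_lvl[ai, 1]
    cx = (ad.sigmoid(sel[:, 0]) + jj.astype(np.float64)) * stride
    cy = (ad.sigmoid(sel[:, 1]) + ii.astype(np.float64)) * stride
    bw = ad.exp(ad.minimum(sel[:, 2], 8.0)) * aw
    bh = ad.exp(ad.minimum(sel[:, 3], 8.0)) * ah
    loss = ciou_loss_t(cx - bw * 0.5, cy - bh * 0.5,
                       cx + bw * 0.5, cy + bh * 0.5, gt)
    return loss, sel


def detection_loss(predictions, targets_per_image, anchors: AnchorSet,
                   weights: LossWeights = LossWeights()):
    """Weighted sum of CIoU box, objectness-BCE and class-BCE terms.

    ``predictions`` is the head output (one (N, A, H, W, 6) tensor per
    level); ``targets_per_image`` is a list (length N) of per-level
    :class:`LevelTargets` from :func:`assign_targets`.

    The objectness BCE balances the positive and negative cell
    populations (0.5 aggregate weight each) and skips the ignore band;
    band cells instead receive a box pull towards their containing
    object (so NMS can absorb whatever fires there) and share the class
    target.  Returns the scalar total and a dict of float components.
    """
    n_images = predictions[0].shape[0]
    total_box = total_obj = total_band = total_cls = total_cls_band = None
    n_pos = n_band = 0
    for lvl, pred in enumerate(predictions):
        stride = STRIDES[lvl]
        lvl_anchors = anchors.level(lvl)
        obj_target = np.stack([targets_per_image[b][lvl].obj
                               for b in range(n_images)])
        wmap = np.zeros_like(obj_target)
        band = _gather(targets_per_image, lvl, "band")
        band_mask = np.zeros_like(obj_target, dtype=bool)
        if band is not None:
            band_mask[(band[0], band[1], band[2], band[3])] = True
        pos_mask = obj_target > 0
        neg_mask = ~pos_mask & ~band_mask
        n_posc = pos_mask.sum()
        w_pos = 0.5 / max(n_posc, 1.0)
        wmap[pos_mask] = w_pos
        # each background cell gets a tenth of the per-positive force:
        # strong enough that objectness cannot generalise upward onto
        # empty background (a population-balanced weight is far too weak
        # for that), and safe because background features genuinely
        # differ from object features
        wmap[neg_mask] = 0.1 * w_pos
        # band cells keep zero objectness weight: pushing them down with
        # any force comparable to the positive signal drags the (feature-
        # sharing) positives down with them, and the box pull below makes
        # whatever fires there an NMS-removable duplicate instead
        obj_elem = ad.bce_with_logits(pred[..., 4], obj_target,
                                      reduction="none")
        obj_term = (obj_elem * wmap).sum()
        total_obj = obj_term if total_obj is None else total_obj + obj_term

        pos = _gather(targets_per_image, lvl, "pos")
        if pos is not None:
            bi, ai, ii, jj, gt = pos
            n_pos += len(bi)
            box_l, sel = _decoded_ciou(pred, (bi, ai, ii, jj),
                                       lvl_anchors, stride, gt)
            box_l = box_l * float(len(bi))
            total_box = box_l if total_box is None else total_box + box_l
            cls_l = ad.bce_with_logits(sel[:, 5], np.ones(len(bi)),
                                       reduction="sum")
            total_cls = cls_l if total_cls is None else total_cls + cls_l
        if band is not None and weights.band_box > 0:
            bi, ai, ii, jj, gt = band
            n_band += len(bi)
            band_l, bsel = _decoded_ciou(pred, (bi, ai, ii, jj),
                                         lvl_anchors, stride, gt)
            band_l = band_l * float(len(bi))
            total_band = band_l if total_band is None else total_band + band_l
            # band cells carry a soft class target of 0.5: it caps the
            # confidence of straddling duplicates at about half so the
            # assigned centre outranks them, while staying high enough
            # that shared-feature drag cannot pull the positives below
            # the detection threshold (a hard 0 target does exactly that).
            # The entropy floor ln 2 is subtracted so the term, like every
            # other component, is zero at its optimum.
            cls_l = ad.bce_with_logits(bsel[:, 5], np.full(len(bi), 0.5),
                                       reduction="sum") \
                + (-math.log(2.0) * len(bi))
            total_cls_band = cls_l if total_cls_band is None \
                else total_cls_band + cls_l
    zero = ad.Tensor(np.float32(0.0))
    box = (total_box * (1.0 / n_pos)) if n_pos else zero
    obj = (total_obj * (1.0 / len(predictions))) if total_obj is not None else zero
    band_box = (total_band * (1.0 / n_band)) if n_band else zero
    # class: positive and band populations carry equal aggregate weight,
    # so the (more numerous) band cells cannot drag the positives' class
    # logit towards their own soft target
    cls_parts = []
    if total_cls is not None and n_pos:
        cls_parts.append(total_cls * (0.5 / n_pos))
    if total_cls_band is not None and n_band:
        cls_parts.append(total_cls_band * (0.5 / n_band))
    cls = zero
    for part in cls_parts:
        cls = cls + part
    total = weights.box * box + weights.objectness * obj \
        + weights.band_box * band_box + weights.class_ * cls
    components = {"box": float(box.data), "objectness": float(obj.data),
                  "band_box": float(band_box.data), "class": float(cls.data),
                  "total": float(total.data), "n_pos": n_pos,
                  "n_band": n_band}
    return total, components
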