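"""Box-loss geometry against a pixel-rasterization oracle, plus target
assignment and the composite loss."""

import numpy as np
import pytest

from wheatear import (Box, LossWeights, assign_targets, ciou_loss,
                      default_anchors, detection_loss, giou_loss, iou,
                      iou_loss)
from wheatear import autodiff as ad
from wheatear.losses import LevelTargets
from wheatear.neck import STRIDES, encode_box


# ---------------------------------------------------------------------------
# rasterization oracle: count pixel centres on a fine grid
# ---------------------------------------------------------------------------

def raster_overlap(a, b, size=1000):
    """(intersection, union, enclosing) areas by pixel counting."""
    xs = (np.arange(size) + 0.5) * (1.0)   # pixel centres on a unit grid
    ys = xs

    def cover(box):
        x1, y1, x2, y2 = box
        cx = (xs >= x1) & (xs < x2)
        cy = (ys >= y1) & (ys < y2)
        return cy[:, None] & cx[None, :]

    ca, cb = cover(a), cover(b)
    enclosing = (min(a[0], b[0]), min(a[1], b[1]),
                 max(a[2], b[2]), max(a[3], b[3]))
    return ((ca & cb).sum(), (ca | cb).sum(), cover(enclosing).sum())


def random_box_pairs(n, rng, lo=50, hi=950, integer=True):
    """Random box pairs on a 1000-px canvas.

    By default corners are integers, the native convention of pixel-level
    annotation: boxes then align with pixel boundaries, so counting pixel
    centres measures their areas *exactly* and the rasterization oracle
    carries no discretisation error of its own.
    """
    pairs = []
    while len(pairs) < n:
        boxes = []
        for _ in range(2):
            x1, y1 = rng.uniform(lo, hi - 80, size=2)
            w, h = rng.uniform(20, 400, size=2)
            box = (x1, y1, min(x1 + w, hi), min(y1 + h, hi))
            if integer:
                box = tuple(float(round(v)) for v in box)
            boxes.append(box)
        a, b = boxes
        if a[2] > a[0] + 1 and a[3] > a[1] + 1 and b[2] > b[0] + 1 \
                and b[3] > b[1] + 1:
            pairs.append((a, b))
    return pairs


class TestGeometry:
    def test_disjoint_boxes_iou_exactly_zero(self):
        assert iou((0, 0, 2, 2), (5, 5, 7, 7)) == 0.0
        assert iou_loss((0, 0, 2, 2), (5, 5, 7, 7)) == 1.0

    def test_identical_boxes(self):
        b = (3.0, 4.0, 10.0, 9.0)
        assert iou(b, b) == 1.0
        assert iou_loss(b, b) == 0.0
        assert giou_loss(b, b) == 0.0
        assert ciou_loss(b, b) == 0.0

    def test_known_overlap_case(self):
        a, b = (0, 0, 2, 2), (1, 1, 3, 3)
        assert iou(a, b) == pytest.approx(1 / 7)
        assert iou_loss(a, b) == pytest.approx(6 / 7)
        assert giou_loss(a, b) == pytest.approx(68 / 63)

    def test_ciou_concentric_same_aspect(self):
        # centre distance 0, identical aspect ratio: only the IoU term acts
        assert ciou_loss((1, 1, 3, 3), (0, 0, 4, 4)) == pytest.approx(0.75)

    def test_giou_exceeds_one_for_far_boxes(self):
        assert giou_loss((0, 0, 1, 1), (10, 10, 11, 11)) > 1.0

    def test_symmetry_of_iou(self, rng):
        for a, b in random_box_pairs(20, rng):
            assert iou(a, b) == pytest.approx(iou(b, a), rel=1e-12)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 2), (1, 1, 3, 3))

    def test_rasterization_oracle_suite(self, rng):
        import math
        for a, b in random_box_pairs(200, rng):
            inter, union, c_area = raster_overlap(a, b)
            iou_pix = inter / union
            assert iou(a, b) == pytest.approx(iou_pix, abs=2e-3)
            giou_pix = 1 - iou_pix + (c_area - union) / c_area
            assert giou_loss(a, b) == pytest.approx(giou_pix, abs=2e-3)
            # ciou: oracle from pixel IoU plus independently computed
            # centre/diagonal/aspect terms
            acx, acy = (a[0] + a[2]) / 2, (a[1] + a[3]) / 2
            bcx, bcy = (b[0] + b[2]) / 2, (b[1] + b[3]) / 2
            rho2 = (acx - bcx) ** 2 + (acy - bcy) ** 2
            ex1, ey1 = min(a[0], b[0]), min(a[1], b[1])
            ex2, ey2 = max(a[2], b[2]), max(a[3], b[3])
            diag2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2
            v = 4 / math.pi ** 2 * (
                math.atan((b[2] - b[0]) / (b[3] - b[1]))
                - math.atan((a[2] - a[0]) / (a[3] - a[1]))) ** 2
            alpha = v / ((1 - iou_pix) + v) if v > 0 else 0.0
            ciou_pix = 1 - iou_pix + rho2 / diag2 + alpha * v
            assert ciou_loss(a, b) == pytest.approx(ciou_pix, abs=2e-3)

    def test_loss_orderings(self, rng):
        for a, b in random_box_pairs(100, rng):
            assert giou_loss(a, b) >= iou_loss(a, b) - 1e-12
            assert ciou_loss(a, b) >= iou_loss(a, b) - 1e-12

    def test_translation_invariance(self, rng):
        for a, b in random_box_pairs(25, rng):
            dx, dy = rng.uniform(-500, 500, size=2)
            a2 = (a[0] + dx, a[1] + dy, a[2] + dx, a[3] + dy)
            b2 = (b[0] + dx, b[1] + dy, b[2] + dx, b[3] + dy)
            assert iou_loss(a2, b2) == pytest.approx(iou_loss(a, b), abs=1e-9)
            assert giou_loss(a2, b2) == pytest.approx(giou_loss(a, b), abs=1e-9)
            assert ciou_loss(a2, b2) == pytest.approx(ciou_loss(a, b), abs=1e-9)

    def test_zero_only_for_identical(self, rng):
        for a, b in random_box_pairs(50, rng):
            if tuple(a) != tuple(b):
                assert giou_loss(a, b) > 0
                assert ciou_loss(a, b) > 0

    def test_ciou_gradient_nonzero_for_disjoint_boxes(self):
        from wheatear.losses import ciou_loss_t
        px1 = ad.Tensor(np.array([0.0]), requires_grad=True)
        py1 = ad.Tensor(np.array([0.0]), requires_grad=True)
        px2 = ad.Tensor(np.array([2.0]), requires_grad=True)
        py2 = ad.Tensor(np.array([2.0]), requires_grad=True)
        gt = np.array([[10.0, 10.0, 12.0, 12.0]])
        ciou_loss_t(px1, py1, px2, py2, gt).backward()
        # the centre-distance term gives a useful pull even at IoU = 0
        assert abs(px1.grad[0]) + abs(px2.grad[0]) > 0

    def test_ciou_tensor_matches_scalar(self, rng):
        from wheatear.losses import ciou_loss_t
        pairs = random_box_pairs(30, rng)
        pa = np.array([p[0] for p in pairs])
        pb = np.array([p[1] for p in pairs])
        ts = [ad.Tensor(pa[:, k]) for k in range(4)]
        got = ciou_loss_t(*ts, pb).item()
        want = np.mean([ciou_loss(a, b) for a, b in pairs])
        assert got == pytest.approx(want, rel=1e-6)


# ---------------------------------------------------------------------------
# assignment and composite loss
# ---------------------------------------------------------------------------

def _grids(size):
    return [(size // s, size // s) for s in STRIDES]


class TestAssignment:
    def test_anchor_sized_box_at_cell_centre(self):
        anchors = default_anchors()
        aw, ah = anchors.level(0)[2]
        cx = cy = 12.0   # inside P3 cell (1, 1)
        gt = [Box(cx - aw / 2, cy - ah / 2, cx + aw / 2, cy + ah / 2)]
        tgt = assign_targets(gt, anchors, _grids(256))
        assert tgt[0].obj[2, 1, 1] == 1.0
        total = sum(t.obj.sum() for t in tgt)
        best_only = tgt[0].obj.sum()
        assert best_only >= 1
        # nothing on a level that the box cannot match
        assert tgt[2].obj.sum() == 0
        assert total == sum(len(t.pos_anchor) for t in tgt)

    def test_empty_ground_truth_all_negative(self):
        tgt = assign_targets([], default_anchors(), _grids(256))
        assert all(t.obj.sum() == 0 and len(t.pos_anchor) == 0 for t in tgt)

    def test_two_boxes_distinct_cells_disjoint_positives(self):
        anchors = default_anchors()
        aw, ah = anchors.level(0)[0]
        boxes = []
        for cx, cy in ((12.0, 12.0), (100.0, 100.0)):
            boxes.append(Box(cx - aw / 2, cy - ah / 2,
                             cx + aw / 2, cy + ah / 2))
        tgt = assign_targets(boxes, anchors, _grids(256))
        # exhaustive check on the P3 grid: positives only at the two cells
        pos = np.argwhere(tgt[0].obj > 0)
        cells = {(int(i), int(j)) for _, i, j in pos}
        assert cells == {(1, 1), (12, 12)}


class TestDetectionLoss:
    def _perfect_setup(self):
        anchors = default_anchors()
        size = 64
        aw, ah = anchors.level(0)[1]
        gt = Box(20.0 - aw / 2, 20.0 - ah / 2, 20.0 + aw / 2, 20.0 + ah / 2)
        targets = [assign_targets([gt], anchors, _grids(size))]
        preds = [ad.Tensor(np.full((1, 3, size // s, size // s, 6), -30.0,
                                   dtype=np.float64)) for s in STRIDES]
        for lvl, t in enumerate(targets[0]):
            for a, i, j, g in zip(t.pos_anchor, t.pos_i, t.pos_j, t.pos_gt):
                tx, ty, tw, th = encode_box(
                    Box(*g), anchors.level(lvl)[a], (i, j), STRIDES[lvl])
                preds[lvl].data[0, a, i, j] = [tx, ty, tw, th, 30.0, 30.0]
            for a, i, j, g in zip(t.band_anchor, t.band_i, t.band_j,
                                  t.band_gt):
                tx, ty, tw, th = encode_box(
                    Box(*g), anchors.level(lvl)[a], (i, j), STRIDES[lvl])
                # band cells: silent objectness, soft (0.5) class target
                # met by a zero logit, duplicate box
                preds[lvl].data[0, a, i, j] = [tx, ty, tw, th, -30.0, 0.0]
        return preds, targets, anchors

    def test_perfect_predictions_give_zero_loss(self):
        preds, targets, anchors = self._perfect_setup()
        total, comps = detection_loss(preds, targets, anchors)
        assert comps["box"] == pytest.approx(0.0, abs=1e-8)
        assert comps["band_box"] == pytest.approx(0.0, abs=1e-6)
        assert comps["total"] == pytest.approx(0.0, abs=1e-6)

    def test_empty_image_box_term_zero(self):
        anchors = default_anchors()
        size = 64
        targets = [assign_targets([], anchors, _grids(size))]
        preds = [ad.Tensor(np.zeros((1, 3, size // s, size // s, 6),
                                    dtype=np.float32)) for s in STRIDES]
        total, comps = detection_loss(preds, targets, anchors)
        assert comps["box"] == 0.0
        assert np.isfinite(comps["total"])

    def test_loss_weights_validate(self):
        with pytest.raises(ValueError):
            LossWeights(box=-1.0)
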