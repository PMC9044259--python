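"""NMS, matching and AP against brute-force oracles."""

import itertools

import numpy as np
import pytest

from wheatear import Box, average_precision, match_detections, nms
from wheatear.boxes import iou_matrix


def B(x1, y1, x2, y2, conf=None):
    return Box(float(x1), float(y1), float(x2), float(y2), confidence=conf)


class TestNMS:
    def test_single_box_kept(self):
        b = B(0, 0, 10, 10, 0.9)
        assert nms([b]) == [b]

    def test_duplicate_keeps_higher_confidence(self):
        lo = B(0, 0, 10, 10, 0.5)
        hi = B(0, 0, 10, 10, 0.9)
        kept = nms([lo, hi], 0.5)
        assert kept == [hi]

    def test_disjoint_boxes_both_kept(self):
        a, b = B(0, 0, 10, 10, 0.9), B(50, 50, 60, 60, 0.8)
        assert set(map(id, nms([a, b], 0.5))) == {id(a), id(b)}

    def test_chain_suppression_is_greedy(self):
        # b overlaps a heavily, c overlaps b but not a: greedy keeps a and c
        a = B(0, 0, 10, 10, 0.9)
        b = B(4, 0, 14, 10, 0.8)
        c = B(9, 0, 19, 10, 0.7)
        kept = nms([a, b, c], 0.3)
        assert kept == [a, c]


class TestMatching:
    def test_exact_predictions(self):
        gt = [B(0, 0, 10, 10), B(30, 30, 40, 45)]
        preds = [B(0, 0, 10, 10, 0.9), B(30, 30, 40, 45, 0.8)]
        tp, fp, fn, _ = match_detections(preds, gt, 0.5)
        assert (tp, fp, fn) == (2, 0, 0)

    def test_no_predictions(self):
        gt = [B(0, 0, 10, 10)]
        tp, fp, fn, flags = match_detections([], gt, 0.5)
        assert (tp, fp, fn) == (0, 0, 1)
        assert len(flags) == 0

    def test_spurious_middle_prediction(self):
        gt = [B(0, 0, 10, 10), B(100, 100, 110, 110)]
        preds = [B(0, 0, 10, 10, 0.9),       # good match
                 B(50, 50, 60, 60, 0.8),     # spurious
                 B(100, 100, 110, 110, 0.7)]  # good match
        tp, fp, fn, flags = match_detections(preds, gt, 0.5)
        assert (tp, fp, fn) == (2, 1, 0)
        assert flags.tolist() == [True, False, True]

    def test_one_to_one(self, rng):
        for _ in range(20):
            gt = [B(x, y, x + w, y + h)
                  for x, y, w, h in rng.uniform(5, 40, size=(4, 4))]
            preds = [B(x, y, x + w, y + h, c) for (x, y, w, h), c in
                     zip(rng.uniform(5, 40, size=(5, 4)),
                         rng.uniform(0, 1, 5))]
            tp, fp, fn, _ = match_detections(preds, gt, 0.3)
            assert tp <= min(len(preds), len(gt))
            assert tp + fp == len(preds) and tp + fn == len(gt)

    def test_greedy_equals_exhaustive_on_small_instances(self, rng):
        """On <=5-box instances the greedy-by-confidence matcher recovers
        the same TP count as exhaustive optimal assignment."""
        mismatches = 0
        for trial in range(60):
            n_gt = int(rng.integers(1, 5))
            n_pr = int(rng.integers(1, 6))
            gt = [B(x, y, x + w, y + h) for x, y, w, h in
                  np.c_[rng.uniform(0, 60, (n_gt, 2)),
                        rng.uniform(10, 40, (n_gt, 2))]]
            preds = [B(x, y, x + w, y + h, c) for (x, y, w, h), c in
                     zip(np.c_[rng.uniform(0, 60, (n_pr, 2)),
                               rng.uniform(10, 40, (n_pr, 2))],
                         rng.uniform(0, 1, n_pr))]
            tp_greedy, _, _, _ = match_detections(preds, gt, 0.5)
            ious = iou_matrix(
                np.array([b.as_xyxy() for b in preds]),
                np.array([b.as_xyxy() for b in gt]))
            best = 0
            for perm in itertools.permutations(range(n_gt)):
                for sub in itertools.permutations(range(n_pr),
                                                  min(n_pr, n_gt)):
                    score = sum(ious[p, g] >= 0.5
                                for p, g in zip(sub, perm))
                    best = max(best, score)
            assert tp_greedy <= best
            mismatches += tp_greedy != best
        # greedy is optimal on these random instances
        assert mismatches == 0


def brute_force_ap(ranked_tp_flags, n_gt):
    """Independent AP: precision envelope integrated over every recall
    step by direct enumeration of ranking prefixes."""
    points = []
    tp = fp = 0
    for flag in ranked_tp_flags:
        tp += flag
        fp += not flag
        points.append((tp / n_gt, tp / (tp + fp)))
    area = 0.0
    r_prev = 0.0
    for r, _ in points:
        if r > r_prev:
            p_env = max(p for rr, p in points if rr >= r)
            area += (r - r_prev) * p_env
            r_prev = r
    return area


class TestAveragePrecision:
    def test_perfect_detector(self):
        gt = [[B(0, 0, 10, 10), B(30, 30, 40, 40)]]
        preds = [[B(0, 0, 10, 10, 0.9), B(30, 30, 40, 40, 0.8)]]
        m = average_precision(preds, gt)
        assert m.ap == 1.0 and m.precision == 1.0 and m.recall == 1.0

    def test_no_true_positive(self):
        gt = [[B(0, 0, 10, 10)]]
        preds = [[B(50, 50, 60, 60, 0.9)]]
        m = average_precision(preds, gt)
        assert m.ap == 0.0 and m.tp == 0 and m.fn == 1

    def test_ranked_tp_fp_tp_gives_five_sixths(self):
        gt = [[B(0, 0, 10, 10), B(100, 100, 110, 110)]]
        preds = [[B(0, 0, 10, 10, 0.9), B(50, 50, 60, 60, 0.8),
                  B(100, 100, 110, 110, 0.7)]]
        m = average_precision(preds, gt)
        assert m.ap == pytest.approx(5 / 6)
        assert m.ap == pytest.approx(brute_force_ap([1, 0, 1], 2))

    @pytest.mark.parametrize("flags,n_gt", [
        ([1, 1, 0, 1, 0], 4), ([0, 1, 1], 2), ([1], 3), ([0, 0, 1, 1], 2)])
    def test_matches_brute_force_enumeration(self, flags, n_gt):
        gt_boxes = [B(i * 50, 0, i * 50 + 10, 10) for i in range(n_gt)]
        preds, g = [], 0
        for rank, f in enumerate(flags):
            conf = 1.0 - rank * 0.1
            if f:
                preds.append(B(g * 50, 0, g * 50 + 10, 10, conf))
                g += 1
            else:
                preds.append(B(1000 + rank * 50, 0, 1010 + rank * 50, 10,
                               conf))
        m = average_precision([preds], [gt_boxes])
        assert m.ap == pytest.approx(brute_force_ap(flags, n_gt))

    def test_invariant_to_monotone_confidence_rescaling(self):
        gt = [[B(0, 0, 10, 10), B(100, 100, 110, 110)]]
        preds = [[B(0, 0, 10, 10, 0.9), B(50, 50, 60, 60, 0.5),
                  B(100, 100, 110, 110, 0.2)]]
        base = average_precision(preds, gt).ap
        squeezed = [[Box(b.x1, b.y1, b.x2, b.y2,
                         confidence=b.confidence ** 3) for b in preds[0]]]
        assert average_precision(squeezed, gt).ap == pytest.approx(base)

    def test_trailing_false_positive_never_raises_ap(self):
        gt = [[B(0, 0, 10, 10), B(100, 100, 110, 110)]]
        preds = [[B(0, 0, 10, 10, 0.9), B(100, 100, 110, 110, 0.7)]]
        base = average_precision(preds, gt).ap
        worse = [preds[0] + [B(500, 500, 510, 510, 0.01)]]
        assert average_precision(worse, gt).ap <= base

    def test_zero_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            average_precision([[B(0, 0, 1, 1, 0.5)]], [[]])

    def test_ap_in_unit_interval(self, rng):
        gt = [[B(0, 0, 20, 20)]]
        preds = [[B(x, y, x + 20, y + 20, c) for (x, y), c in
                  zip(rng.uniform(0, 30, (6, 2)), rng.uniform(0, 1, 6))]]
        m = average_precision(preds, gt, 0.5)
        assert 0.0 <= m.ap <= 1.0
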