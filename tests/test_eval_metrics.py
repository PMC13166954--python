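"""IoU, matching, precision/recall, AP with brute-force oracle, confusion."""

import numpy as np
import pytest

from eyolo.eval_metrics import (
    MatchResult, accuracy, average_precision, background_true_negatives,
    confusion_matrix, evaluate_detections, iou, map_at, map_range,
    match_detections, precision_recall_f1,
)


class TestIoU:
    def test_identical(self):
        assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0

    def test_corner_overlap_one_seventh(self):
        assert iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_disjoint(self):
        assert iou((0, 0, 1, 1), (2, 2, 3, 3)) == 0.0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 1), (0, 0, 1, 1))


def det(img, cls, score, box):
    return (img, cls, score, box)


def truth(img, cls, box):
    return (img, cls, box)


class TestMatching:
    def test_perfect_detections(self):
        truths = [truth(0, 0, (0, 0, 10, 10)), truth(0, 1, (20, 20, 30, 30))]
        dets = [det(0, 0, 0.9, (0, 0, 10, 10)), det(0, 1, 0.8, (20, 20, 30, 30))]
        m = match_detections(dets, truths, 0.5)
        assert (m.c_pos, m.m_pos, m.m_neg) == (2, 0, 0)

    def test_double_detection_counts_one_fp(self):
        truths = [truth(0, 0, (0, 0, 10, 10))]
        dets = [det(0, 0, 0.9, (0, 0, 10, 10)), det(0, 0, 0.8, (1, 1, 11, 11))]
        m = match_detections(dets, truths, 0.5)
        assert (m.c_pos, m.m_pos, m.m_neg) == (1, 1, 0)
        assert m.pairs[0][0][2] == 0.9  # higher-scored one matched

    def test_wrong_class_is_fp_and_fn(self):
        truths = [truth(0, 0, (0, 0, 10, 10))]
        dets = [det(0, 3, 0.9, (0, 0, 10, 10))]
        m = match_detections(dets, truths, 0.5)
        assert (m.c_pos, m.m_pos, m.m_neg) == (0, 1, 1)

    def test_one_to_one_invariant(self, rng):
        truths = [truth(0, int(rng.integers(0, 3)),
                        tuple(np.sort(rng.uniform(0, 50, 2)))
                        + tuple(np.sort(rng.uniform(50, 99, 2))))
                  for _ in range(10)]
        truths = [(i, c, (b[0], b[2], b[1], b[3]))
                  for (i, c, b) in truths]
        dets = [det(0, int(rng.integers(0, 3)), float(rng.random()),
                    (x, y, x + 10, y + 10))
                for x, y in rng.uniform(0, 80, (15, 2))]
        m = match_detections(dets, truths, 0.3)
        assert m.c_pos <= min(len(dets), len(truths))
        assert m.c_pos + m.m_pos == len(dets)
        assert m.c_pos + m.m_neg == len(truths)


class TestPrecisionRecallF1:
    def test_direct_formula(self):
        p, r, f1 = precision_recall_f1(MatchResult(9, 1, 1))
        assert (p, r, f1) == (0.9, 0.9, pytest.approx(0.9))

    def test_perfect(self):
        assert precision_recall_f1(MatchResult(5, 0, 0)) == (1.0, 1.0, 1.0)

    def test_zero_convention(self):
        assert precision_recall_f1(MatchResult(0, 3, 2)) == (0.0, 0.0, 0.0)

    def test_f1_between_min_and_max(self, rng):
        for _ in range(30):
            m = MatchResult(*(int(v) for v in rng.integers(0, 20, 3)))
            p, r, f1 = precision_recall_f1(m)
            assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12


class TestAccuracy:
    def test_direct_formula(self):
        assert accuracy(MatchResult(9, 1, 0, c_neg=90)) == pytest.approx(0.99)

    def test_no_errors(self):
        assert accuracy(MatchResult(5, 0, 0, c_neg=10)) == 1.0

    def test_only_errors(self):
        assert accuracy(MatchResult(0, 2, 3, c_neg=0)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(MatchResult(0, 0, 0, c_neg=0))

    def test_background_counter(self):
        scores = [np.array([[0.1, 0.9], [0.6, 0.05]])]
        targets = [np.array([[0, 1], [0, 0]])]
        # three negative locations, two of them below threshold 0.25
        assert background_true_negatives(scores, targets, 0.25) == 2


def oracle_average_precision(dets, truths, cls, tau):
    """Brute-force oracle: enumerate the cumulative PR sequence directly and
    sum rectangle areas under the running-max precision envelope."""
    from eyolo.eval_metrics import iou as _iou
    cls_truths = [t for t in truths if t[1] == cls]
    order = sorted([d for d in dets if d[1] == cls],
                   key=lambda d: -d[2])
    used = set()
    seq = []
    for d in order:
        best, bj = 0.0, None
        for j, t in enumerate(cls_truths):
            if j in used or t[0] != d[0]:
                continue
            v = _iou(d[3], t[2])
            if v > best:
                best, bj = v, j
        if bj is not None and best >= tau:
            used.add(bj)
            seq.append(True)
        else:
            seq.append(False)
    n_truth = len(cls_truths)
    points = []
    tp = fp = 0
    for is_tp in seq:
        tp += is_tp
        fp += not is_tp
        points.append((tp / n_truth, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for r, _p in points:
        if r > prev_r:
            # best precision at any recall >= r (the envelope)
            ap += (r - prev_r) * max(p2 for r2, p2 in points if r2 >= r)
            prev_r = r
    return ap


class TestAveragePrecision:
    def test_perfect_detector(self):
        truths = [truth(0, 0, (0, 0, 10, 10)), truth(1, 0, (5, 5, 15, 15))]
        dets = [det(0, 0, 0.9, (0, 0, 10, 10)), det(1, 0, 0.95, (5, 5, 15, 15))]
        assert average_precision(dets, truths, 0) == 1.0

    def test_tp_fp_tp_worked_example(self):
        """Ranked [TP, FP, TP] with 2 truths: AP = 0.5*1 + 0.5*(2/3)."""
        truths = [truth(0, 0, (0, 0, 10, 10)), truth(0, 0, (40, 40, 50, 50))]
        dets = [det(0, 0, 0.9, (0, 0, 10, 10)),
                det(0, 0, 0.8, (70, 70, 80, 80)),
                det(0, 0, 0.7, (40, 40, 50, 50))]
        assert average_precision(dets, truths, 0) == pytest.approx(
            0.5 * 1 + 0.5 * (2 / 3))

    def test_all_false_gives_zero(self):
        truths = [truth(0, 0, (0, 0, 10, 10))]
        dets = [det(0, 0, 0.9, (50, 50, 60, 60))]
        assert average_precision(dets, truths, 0) == 0.0

    def test_no_truths_rejected(self):
        with pytest.raises(ValueError):
            average_precision([], [truth(0, 1, (0, 0, 5, 5))], 0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            truths = [truth(int(rng.integers(0, 2)), 0,
                            (x, y, x + 10, y + 10))
                      for x, y in rng.uniform(0, 80, (int(rng.integers(1, 6)), 2))]
            dets = [det(int(rng.integers(0, 2)), 0, float(rng.random()),
                        (x, y, x + 10, y + 10))
                    for x, y in rng.uniform(0, 80, (int(rng.integers(1, 20)), 2))]
            ours = average_precision(dets, truths, 0, 0.5)
            ref = oracle_average_precision(dets, truths, 0, 0.5)
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_adding_fp_never_helps(self, rng):
        truths = [truth(0, 0, (0, 0, 10, 10)), truth(0, 0, (30, 30, 40, 40))]
        dets = [det(0, 0, 0.9, (0, 0, 10, 10)), det(0, 0, 0.6, (30, 30, 40, 40))]
        base = average_precision(dets, truths, 0)
        for score in (0.95, 0.75, 0.4):
            worse = dets + [det(0, 0, score, (60, 60, 70, 70))]
            assert average_precision(worse, truths, 0) <= base + 1e-12


class TestMAP:
    def test_perfect_detector_all_thresholds(self):
        truths = [truth(0, c, (10 * c, 0, 10 * c + 8, 8)) for c in range(6)]
        dets = [det(0, c, 0.9, (10 * c, 0, 10 * c + 8, 8)) for c in range(6)]
        assert map_at(dets, truths, 0.5) == 1.0
        assert map_range(dets, truths) == 1.0

    def test_mean_of_per_class_aps(self):
        truths = [truth(0, 0, (0, 0, 10, 10)), truth(0, 1, (30, 30, 40, 40))]
        dets = [det(0, 0, 0.9, (0, 0, 10, 10)),      # class 0: AP = 1
                det(0, 1, 0.9, (60, 60, 70, 70)),    # class 1: FP then TP
                det(0, 1, 0.8, (30, 30, 40, 40))]    # -> AP = 0.5
        with pytest.warns(RuntimeWarning):
            assert map_at(dets, truths, 0.5) == pytest.approx(0.75)

    def test_range_map_no_larger_than_map50(self, rng):
        truths, dets = [], []
        for i in range(8):
            x, y = rng.uniform(0, 80, 2)
            truths.append(truth(0, int(rng.integers(0, 2)), (x, y, x + 12, y + 12)))
            dx, dy = rng.uniform(-3, 3, 2)
            dets.append(det(0, truths[-1][1], float(rng.random()),
                            (x + dx, y + dy, x + 12 + dx, y + 12 + dy)))
        assert map_range(dets, truths) <= map_at(dets, truths, 0.5) + 1e-12

    def test_empty_truths_rejected(self):
        with pytest.raises(ValueError):
            map_at([], [], 0.5)


class TestConfusionMatrix:
    def test_perfect_detector_is_diagonal(self):
        truths = [truth(0, c, (12 * c, 0, 12 * c + 8, 8)) for c in range(6)]
        dets = [det(0, c, 0.9, (12 * c, 0, 12 * c + 8, 8)) for c in range(6)]
        cm = confusion_matrix(dets, truths)
        assert np.array_equal(cm.matrix, np.eye(6, dtype=int))
        assert cm.unmatched_truth.sum() == 0

    def test_cross_class_confusion_recorded(self):
        truths = [truth(0, 0, (0, 0, 10, 10))]
        dets = [det(0, 3, 0.9, (0, 0.5, 10, 10))]  # IoU 0.9, RBC called ARBC
        cm = confusion_matrix(dets, truths)
        assert cm.matrix[0, 3] == 1
        assert cm.matrix.sum() == 1

    def test_row_sums_conserved_on_random_scenes(self, rng):
        truths, dets = [], []
        for img in range(30):
            for _ in range(int(rng.integers(1, 6))):
                x, y = rng.uniform(0, 80, 2)
                c = int(rng.integers(0, 6))
                truths.append(truth(img, c, (x, y, x + 10, y + 10)))
                if rng.random() < 0.8:  # jittered, sometimes missing
                    dx, dy = rng.uniform(-4, 4, 2)
                    pc = c if rng.random() < 0.8 else int(rng.integers(0, 6))
                    dets.append(det(img, pc, float(rng.random()),
                                    (x + dx, y + dy, x + 10 + dx, y + 10 + dy)))
        cm = confusion_matrix(dets, truths, 0.5)
        per_class_truths = np.bincount([t[1] for t in truths], minlength=6)
        assert np.array_equal(cm.matrix.sum(axis=1) + cm.unmatched_truth,
                              per_class_truths)


def test_evaluate_detections_report_structure():
    truths = [truth(0, 0, (0, 0, 10, 10)), truth(0, 3, (30, 30, 42, 42))]
    dets = [det(0, 0, 0.9, (0, 0, 10, 10)), det(0, 3, 0.8, (31, 31, 42, 42))]
    rep = evaluate_detections(dets, truths, c_neg=50)
    assert rep.map50 == 1.0
    assert 0 < rep.mean_iou <= 1
    assert rep.accuracy == 1.0
    assert "mAP@0.5" in rep.to_text()
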