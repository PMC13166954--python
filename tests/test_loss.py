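"""Loss closed forms, target assignment, and gradient sanity."""

import math

import numpy as np
import pytest

from eyolo.loss import (
    BoxPair, LossWeights, assign_targets, ciou_loss, ciou_loss_grad, cls_loss,
    detection_loss_and_grads, offset_reg_loss, total_loss,
)
from eyolo.smear_synth import Annotation, CellClass


class TestCIoU:
    def test_identical_boxes_give_zero(self):
        assert ciou_loss(BoxPair((1, 1, 3, 4), (1, 1, 3, 4))) == pytest.approx(0.0)

    def test_concentric_squares_closed_form(self):
        """IoU = 0.25, centres coincide, both square: loss = 0.75."""
        pair = BoxPair((0, 0, 2, 2), (0.5, 0.5, 1.5, 1.5))
        assert pair.rho == 0.0
        assert pair.v == pytest.approx(0.0)
        assert pair.iou == pytest.approx(0.25)
        assert ciou_loss(pair) == pytest.approx(0.75)

    def test_disjoint_boxes_at_least_one(self):
        assert ciou_loss(BoxPair((0, 0, 1, 1), (5, 5, 6, 6))) >= 1.0

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BoxPair((0, 0, 0, 1), (0, 0, 1, 1))

    def test_lower_bound_one_minus_iou(self, rng):
        for _ in range(50):
            a = np.sort(rng.uniform(0, 10, 2))
            b = np.sort(rng.uniform(0, 10, 2))
            c = np.sort(rng.uniform(0, 10, 2))
            d = np.sort(rng.uniform(0, 10, 2))
            if a[1] - a[0] < 0.1 or b[1] - b[0] < 0.1 \
                    or c[1] - c[0] < 0.1 or d[1] - d[0] < 0.1:
                continue
            pair = BoxPair((a[0], b[0], a[1], b[1]), (c[0], d[0], c[1], d[1]))
            assert ciou_loss(pair) >= 1.0 - pair.iou - 1e-12

    def test_gradient_matches_finite_differences(self, rng):
        for _ in range(20):
            pred = np.array([[0, 0, 0, 0]], dtype=float)
            pred[0, :2] = rng.uniform(0, 5, 2)
            pred[0, 2:] = pred[0, :2] + rng.uniform(0.5, 5, 2)
            truth = np.array([[0, 0, 0, 0]], dtype=float)
            truth[0, :2] = rng.uniform(0, 5, 2)
            truth[0, 2:] = truth[0, :2] + rng.uniform(0.5, 5, 2)
            _, grad = ciou_loss_grad(pred, truth)
            eps = 1e-6
            for k in range(4):
                pp, pm = pred.copy(), pred.copy()
                pp[0, k] += eps
                pm[0, k] -= eps
                num = (ciou_loss_grad(pp, truth)[0][0]
                       - ciou_loss_grad(pm, truth)[0][0]) / (2 * eps)
                assert abs(grad[0, k] - num) / (abs(num) + 1e-3) < 1e-3


class TestClsLoss:
    def test_one_hot_prediction_is_zero(self):
        p = np.zeros(6)
        p[2] = 1.0
        assert cls_loss(p, 2) == pytest.approx(0.0)

    def test_uniform_prediction_closed_form(self):
        assert cls_loss(np.full(6, 1 / 6), 3) == pytest.approx(
            math.log(6), abs=1e-4)

    def test_zero_probability_is_guarded(self):
        p = np.zeros(6)
        p[0] = 1.0
        val = cls_loss(p, 5)
        assert np.isfinite(val) and val > 20  # -log(1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.dirichlet(np.ones(6))
        perm = rng.permutation(6)
        for cls in range(6):
            assert cls_loss(p, cls) == pytest.approx(
                cls_loss(p[np.argsort(perm)], int(perm[cls])))

    def test_malformed_vector_rejected(self):
        with pytest.raises(ValueError):
            cls_loss(np.full(6, 0.5), 0)


class TestOffsetReg:
    def test_zero_offsets(self):
        assert offset_reg_loss(np.zeros((4, 4, 9, 2))) == 0.0

    def test_single_vector_squared_norm(self):
        assert offset_reg_loss(np.array([[3.0, 4.0]])) == pytest.approx(25.0)

    def test_quadratic_homogeneity(self, rng):
        o = rng.standard_normal((3, 5, 2))
        base = offset_reg_loss(o)
        assert offset_reg_loss(2.5 * o) == pytest.approx(2.5 ** 2 * base)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            offset_reg_loss(np.array([[np.inf, 0.0]]))


class TestAssignTargets:
    def test_empty_image_all_negative(self):
        out = assign_targets((64, 64), [])
        for obj, cls, _ in out.values():
            assert obj.sum() == 0 and np.all(cls == -1)

    def test_single_box_over_single_centre(self):
        # stride-8 centres sit at 4, 12, 20, ...; box [9,15]^2 holds (12,12)
        ann = Annotation(CellClass.WBC, (12 / 64, 12 / 64, 6 / 64, 6 / 64))
        out = assign_targets((64, 64), [ann])
        obj8, cls8, box8 = out[8]
        assert obj8.sum() == 1
        assert cls8[1, 1] == int(CellClass.WBC)
        assert np.allclose(box8[1, 1], ann.to_pixels(64, 64))
        assert out[16][0].sum() == 0 and out[32][0].sum() == 0

    def test_nested_boxes_prefer_smaller(self):
        big = Annotation(CellClass.RBC, (0.5, 0.5, 0.6, 0.6))
        small = Annotation(CellClass.PL, (12 / 64, 12 / 64, 10 / 64, 10 / 64))
        out = assign_targets((64, 64), [big, small])
        assert out[8][1][1, 1] == int(CellClass.PL)

    def test_size_ranges_route_scales(self):
        large = Annotation(CellClass.AWBC, (0.5, 0.5, 70 / 256, 70 / 256))
        out = assign_targets((256, 256), [large])
        assert out[8][0].sum() == 0       # 70 px routes to stride 16
        assert out[16][0].sum() > 0
        assert out[32][0].sum() == 0


class TestTotalLoss:
    def test_weighted_sum_example(self):
        bd = total_loss(l_reg=0.2, l_cls=1.0, l_det=0.5)
        assert bd.total() == pytest.approx(0.05 * 0.2 + 1.0 + 0.5)
        assert bd.total() == pytest.approx(1.51)

    def test_all_zero(self):
        assert total_loss(0, 0, 0).total() == 0.0

    def test_unweighted_channel_reproduces_epoch_table_total(self):
        """The published epoch table's totals are unweighted sums of the
        three terms (0.12 + 0.15 + 0.29 = 0.56); the weighted training sum
        differs because lambda_reg = 0.05."""
        bd = total_loss(l_reg=0.29, l_cls=0.15, l_det=0.12)
        assert bd.total_unweighted == pytest.approx(0.56)
        assert bd.total() != pytest.approx(0.56)

    def test_linear_in_each_component(self, rng):
        r, c, d = rng.uniform(0.1, 2.0, 3)
        w = LossWeights()
        base = total_loss(r, c, d).total(w)
        assert total_loss(2 * r, c, d).total(w) == pytest.approx(
            base + w.lambda_reg * r)
        assert total_loss(r, 2 * c, d).total(w) == pytest.approx(
            base + w.lambda_cls * c)
        assert total_loss(r, c, 2 * d).total(w) == pytest.approx(
            base + w.lambda_det * d)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            total_loss(-0.1, 0.0, 0.0)


class TestDenseLossGradients:
    def test_head_gradients_match_finite_differences(self, rng):
        """End-to-end check of the dense batch loss gradients (objectness,
        class logits, box distances) on one small image."""
        anns = [Annotation(CellClass.RBC, (12 / 64, 12 / 64, 14 / 64, 12 / 64)),
                Annotation(CellClass.APL, (40 / 64, 44 / 64, 10 / 64, 10 / 64))]
        raw = {s: rng.standard_normal((11, 1, 64 // s, 64 // s)) * 0.5
               for s in (8, 16, 32)}
        bd, grads, _ = detection_loss_and_grads(raw, [anns], (64, 64))

        def loss_of(raw2):
            bd2, _, _ = detection_loss_and_grads(raw2, [anns], (64, 64))
            return bd2.total()

        eps = 1e-4
        rng2 = np.random.default_rng(1)
        for s in (8, 16, 32):
            for _ in range(6):
                c = rng2.integers(0, 11)
                y = rng2.integers(0, 64 // s)
                x = rng2.integers(0, 64 // s)
                rp = {k: v.copy() for k, v in raw.items()}
                rp[s][c, 0, y, x] += eps
                rm = {k: v.copy() for k, v in raw.items()}
                rm[s][c, 0, y, x] -= eps
                num = (loss_of(rp) - loss_of(rm)) / (2 * eps)
                assert abs(grads[s][c, 0, y, x] - num) < 1e-3 * max(1, abs(num))

    def test_no_ground_truth_gives_zero_det_loss(self, rng):
        raw = {s: rng.standard_normal((11, 1, 32 // s, 32 // s))
               for s in (8, 16, 32)}
        bd, _, _ = detection_loss_and_grads(raw, [[]], (32, 32))
        assert bd.l_det == 0.0
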