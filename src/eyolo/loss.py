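"""Composite training objective: CIoU localization, cross-entropy
classification, deformable-offset regularization.

    L_total = lambda_reg * L_reg + lambda_cls * L_cls + lambda_det * L_det

L_det is the CIoU loss averaged over positive locations; L_cls is
softmax cross-entropy at positive locations plus the objectness
binary cross-entropy over all locations (an addition required by the
anchor-free head -- bookkept inside the classification term); L_reg is
the mean squared L2 norm of every deformable sampling offset.  Training
uses the weighted sum; the unweighted sum of the three terms is logged
alongside it, matching how epoch tables conventionally report totals.

Target assignment is centre-based: a grid location is positive iff its
centre lies inside a ground-truth box whose longest side falls in the
scale's size range; among multiple containing boxes the smallest wins.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from eyolo.elastic_net import STRIDES

# longest-side ranges (pixels) routing objects to the three scales
SCALE_RANGES = ((0.0, 64.0), (64.0, 128.0), (128.0, float("inf")))

_LOG_GUARD = 1e-12


@dataclasses.dataclass(frozen=True)
class LossWeights:
    lambda_reg: float = 0.05
    lambda_cls: float = 1.0
    lambda_det: float = 1.0

    def __post_init__(self):
        if min(self.lambda_reg, self.lambda_cls, self.lambda_det) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclasses.dataclass(frozen=True)
class LossBreakdown:
    l_det: float
    l_cls: float
    l_reg: float

    @property
    def total_unweighted(self) -> float:
        return self.l_det + self.l_cls + self.l_reg

    def total(self, weights: LossWeights = LossWeights()) -> float:
        return (weights.lambda_reg * self.l_reg
                + weights.lambda_cls * self.l_cls
                + weights.lambda_det * self.l_det)


def total_loss(l_reg: float, l_cls: float, l_det: float,
               weights: LossWeights = LossWeights()) -> LossBreakdown:
    """Weighted sum of nonnegative components (also carries the unweighted sum)."""
    if min(l_reg, l_cls, l_det) < 0:
        raise ValueError("loss components must be >= 0")
    return LossBreakdown(l_det=l_det, l_cls=l_cls, l_reg=l_reg)


# ---------------------------------------------------------------------------
# CIoU
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class BoxPair:
    """Predicted and ground-truth boxes, corner format (x1, y1, x2, y2)."""

    pred: tuple[float, float, float, float]
    truth: tuple[float, float, float, float]

    def __post_init__(self):
        for name, (x1, y1, x2, y2) in (("pred", self.pred), ("truth", self.truth)):
            if x2 <= x1 or y2 <= y1:
                raise ValueError(f"{name} box has non-positive area")

    @property
    def iou(self) -> float:
        return float(_ciou_terms(np.array([self.pred]), np.array([self.truth]))[0][0])

    @property
    def rho(self) -> float:
        """Euclidean distance between box centres."""
        (px, py), (tx, ty) = _centre(self.pred), _centre(self.truth)
        return math.hypot(px - tx, py - ty)

    @property
    def enclosing_diagonal(self) -> float:
        """Diagonal length c of the minimum enclosing box."""
        cw = max(self.pred[2], self.truth[2]) - min(self.pred[0], self.truth[0])
        ch = max(self.pred[3], self.truth[3]) - min(self.pred[1], self.truth[1])
        return math.hypot(cw, ch)

    @property
    def v(self) -> float:
        """Aspect-ratio deviation 4/pi^2 (atan(w*/h*) - atan(w/h))^2."""
        return float(_ciou_terms(np.array([self.pred]), np.array([self.truth]))[2][0])

    @property
    def alpha(self) -> float:
        """Balance factor v / ((1 - IoU) + v)."""
        iou, _, v = _ciou_terms(np.array([self.pred]), np.array([self.truth]))
        denom = (1.0 - iou[0]) + v[0]
        return float(v[0] / denom) if denom > 0 else 0.0


def _centre(box):
    return (box[0] + box[2]) / 2.0, (box[1] + box[3]) / 2.0


def _ciou_terms(pred: np.ndarray, truth: np.ndarray):
    """(iou, rho^2/c^2, v) for (P, 4) corner-box arrays."""
    ix1 = np.maximum(pred[:, 0], truth[:, 0])
    iy1 = np.maximum(pred[:, 1], truth[:, 1])
    ix2 = np.minimum(pred[:, 2], truth[:, 2])
    iy2 = np.minimum(pred[:, 3], truth[:, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_p = (pred[:, 2] - pred[:, 0]) * (pred[:, 3] - pred[:, 1])
    area_t = (truth[:, 2] - truth[:, 0]) * (truth[:, 3] - truth[:, 1])
    union = area_p + area_t - inter
    iou = inter / union
    pcx, pcy = (pred[:, 0] + pred[:, 2]) / 2, (pred[:, 1] + pred[:, 3]) / 2
    tcx, tcy = (truth[:, 0] + truth[:, 2]) / 2, (truth[:, 1] + truth[:, 3]) / 2
    rho2 = (pcx - tcx) ** 2 + (pcy - tcy) ** 2
    cw = np.maximum(pred[:, 2], truth[:, 2]) - np.minimum(pred[:, 0], truth[:, 0])
    ch = np.maximum(pred[:, 3], truth[:, 3]) - np.minimum(pred[:, 1], truth[:, 1])
    c2 = cw ** 2 + ch ** 2
    w_p, h_p = pred[:, 2] - pred[:, 0], pred[:, 3] - pred[:, 1]
    w_t, h_t = truth[:, 2] - truth[:, 0], truth[:, 3] - truth[:, 1]
    v = (4.0 / math.pi ** 2) * (np.arctan(w_t / h_t) - np.arctan(w_p / h_p)) ** 2
    return iou, rho2 / np.maximum(c2, 1e-12), v


def ciou_loss(pair: BoxPair) -> float:
    """1 - IoU + alpha*v + rho^2/c^2 for one box pair."""
    loss, _ = ciou_loss_grad(np.array([pair.pred], dtype=np.float64),
                             np.array([pair.truth], dtype=np.float64))
    return float(loss[0])


def ciou_loss_grad(pred: np.ndarray, truth: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized CIoU loss and its gradient w.r.t. predicted corners.

    ``pred``/``truth`` are (P, 4) corner boxes with positive area.  The
    balance factor alpha = v / ((1 - IoU) + v) is differentiated through,
    so the gradient matches finite differences of the loss exactly.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if np.any(pred[:, 2] <= pred[:, 0]) or np.any(pred[:, 3] <= pred[:, 1]) \
            or np.any(truth[:, 2] <= truth[:, 0]) or np.any(truth[:, 3] <= truth[:, 1]):
        raise ValueError("degenerate (zero-area) box")
    x1, y1, x2, y2 = pred.T
    tx1, ty1, tx2, ty2 = truth.T
    ix1, iy1 = np.maximum(x1, tx1), np.maximum(y1, ty1)
    ix2, iy2 = np.minimum(x2, tx2), np.minimum(y2, ty2)
    iw, ih = np.clip(ix2 - ix1, 0, None), np.clip(iy2 - iy1, 0, None)
    inter = iw * ih
    w_p, h_p = x2 - x1, y2 - y1
    w_t, h_t = tx2 - tx1, ty2 - ty1
    area_p, area_t = w_p * h_p, w_t * h_t
    union = area_p + area_t - inter
    iou = inter / union

    # d inter / d corners (only when the intersection is non-empty)
    nz = (iw > 0) & (ih > 0)
    di_dx1 = -ih * ((x1 > tx1) & nz)
    di_dx2 = ih * ((x2 < tx2) & nz)
    di_dy1 = -iw * ((y1 > ty1) & nz)
    di_dy2 = iw * ((y2 < ty2) & nz)
    da_dx1, da_dx2 = -h_p, h_p
    da_dy1, da_dy2 = -w_p, w_p

    def diou(di, da):
        du = da - di
        return (di * union - inter * du) / union ** 2

    diou_d = np.stack([diou(di_dx1, da_dx1), diou(di_dy1, da_dy1),
                       diou(di_dx2, da_dx2), diou(di_dy2, da_dy2)], axis=1)

    # centre-distance term rho^2 / c^2
    pcx, pcy = (x1 + x2) / 2, (y1 + y2) / 2
    tcx, tcy = (tx1 + tx2) / 2, (ty1 + ty2) / 2
    rho2 = (pcx - tcx) ** 2 + (pcy - tcy) ** 2
    cw = np.maximum(x2, tx2) - np.minimum(x1, tx1)
    ch = np.maximum(y2, ty2) - np.minimum(y1, ty1)
    c2 = np.maximum(cw ** 2 + ch ** 2, 1e-12)
    drho2_d = np.stack([(pcx - tcx), (pcy - tcy),
                        (pcx - tcx), (pcy - tcy)], axis=1)
    dcw_d = np.stack([-(x1 < tx1).astype(float), np.zeros_like(x1),
                      (x2 > tx2).astype(float), np.zeros_like(x1)], axis=1)
    dch_d = np.stack([np.zeros_like(x1), -(y1 < ty1).astype(float),
                      np.zeros_like(x1), (y2 > ty2).astype(float)], axis=1)
    dc2_d = 2 * cw[:, None] * dcw_d + 2 * ch[:, None] * dch_d
    dterm2_d = drho2_d / c2[:, None] - (rho2 / c2 ** 2)[:, None] * dc2_d

    # aspect-ratio term alpha * v with alpha = v / ((1 - IoU) + v)
    delta = np.arctan(w_t / h_t) - np.arctan(w_p / h_p)
    v = (4.0 / math.pi ** 2) * delta ** 2
    denom = np.maximum(1.0 - iou + v, 1e-12)
    alpha = v / denom
    dv_dw = -(8.0 / math.pi ** 2) * delta * h_p / (w_p ** 2 + h_p ** 2)
    dv_dh = (8.0 / math.pi ** 2) * delta * w_p / (w_p ** 2 + h_p ** 2)
    dv_d = np.stack([-dv_dw, -dv_dh, dv_dw, dv_dh], axis=1)
    # d(alpha)/d = [dv*(1 - IoU) + v*dIoU] / denom^2
    dalpha_d = (dv_d * (1.0 - iou)[:, None] + v[:, None] * diou_d) \
        / (denom ** 2)[:, None]

    loss = 1.0 - iou + rho2 / c2 + alpha * v
    grad = -diou_d + dterm2_d + alpha[:, None] * dv_d + v[:, None] * dalpha_d
    return loss, grad


# ---------------------------------------------------------------------------
# Classification and offset regularization
# ---------------------------------------------------------------------------

def cls_loss(predicted_probs, target_class: int) -> float:
    """Cross-entropy -sum_i y_i log(p_i) with one-hot target, log guarded."""
    p = np.asarray(predicted_probs, dtype=np.float64)
    if p.ndim != 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("predicted_probs must be a probability vector")
    if not 0 <= target_class < p.shape[0]:
        raise ValueError(f"target class {target_class} out of range")
    return float(-np.log(max(p[target_class], _LOG_GUARD)))


def offset_reg_loss(offsets) -> float:
    """Mean over offset vectors of the squared L2 norm ||Delta p||_2^2.

    Accepts one array with trailing axis 2, or a collection of such arrays
    (e.g. one per deformable layer).
    """
    if isinstance(offsets, np.ndarray):
        offsets = [offsets]
    chunks = []
    for o in offsets:
        o = np.asarray(o, dtype=np.float64)
        if o.shape[-1] != 2:
            raise ValueError("offset vectors must have trailing dimension 2")
        if not np.all(np.isfinite(o)):
            raise ValueError("offsets must be finite")
        chunks.append((o ** 2).sum(axis=-1).reshape(-1))
    if not chunks:
        return 0.0
    norms = np.concatenate(chunks)
    return float(norms.mean()) if norms.size else 0.0


# ---------------------------------------------------------------------------
# Target assignment (anchor-free, centre-based)
# ---------------------------------------------------------------------------

def assign_targets(image_size: tuple[int, int], annotations,
                   strides=STRIDES, scale_ranges=SCALE_RANGES):
    """Per-scale dense targets for one image.

    Returns {stride: (obj (h, w) float 0/1, cls (h, w) int (-1 for negative),
    box (h, w, 4) corner-format pixels)}.
    """
    H, W = image_size
    boxes, classes = [], []
    for ann in annotations:
        boxes.append(ann.to_pixels(W, H))
        classes.append(int(ann.cell_class))
    boxes = np.array(boxes, dtype=np.float64).reshape(-1, 4)
    classes = np.array(classes, dtype=np.int64)
    longest = np.maximum(boxes[:, 2] - boxes[:, 0], boxes[:, 3] - boxes[:, 1]) \
        if len(boxes) else np.zeros(0)
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1]) \
        if len(boxes) else np.zeros(0)

    out = {}
    for stride, (lo, hi) in zip(strides, scale_ranges):
        h, w = H // stride, W // stride
        obj = np.zeros((h, w), dtype=np.float64)
        cls = np.full((h, w), -1, dtype=np.int64)
        box_t = np.zeros((h, w, 4), dtype=np.float64)
        if len(boxes):
            in_range = (longest >= lo) & (longest < hi)
            cy = (np.arange(h) + 0.5) * stride
            cx = (np.arange(w) + 0.5) * stride
            inside = ((cx[None, None, :] >= boxes[:, 0, None, None])
                      & (cx[None, None, :] <= boxes[:, 2, None, None])
                      & (cy[None, :, None] >= boxes[:, 1, None, None])
                      & (cy[None, :, None] <= boxes[:, 3, None, None])
                      & in_range[:, None, None])
            # smallest containing box wins
            masked_area = np.where(inside, areas[:, None, None], np.inf)
            best = masked_area.argmin(axis=0)
            has = inside.any(axis=0)
            obj[has] = 1.0
            cls[has] = classes[best[has]]
            box_t[has] = boxes[best[has]]
        out[stride] = (obj, cls, box_t)
    return out


# ---------------------------------------------------------------------------
# Dense batch loss over raw head outputs (training path)
# ---------------------------------------------------------------------------

def detection_loss_and_grads(raw_outputs: dict[int, np.ndarray],
                             batch_annotations,
                             image_size: tuple[int, int],
                             num_classes: int = 6,
                             offset_fields: list[np.ndarray] | None = None,
                             weights: LossWeights = LossWeights(),
                             focal_gamma: float = 0.0):
    """Loss breakdown plus gradients w.r.t. raw head outputs and offsets.

    ``raw_outputs``: {stride: (4 + 1 + nc, N, h, w)} -- box log-distances,
    objectness logit, class logits.  ``offset_fields``: the deformable
    layers' Delta-p maps ((2|S|, N, h, w) each) entering L_reg.  Returns
    (LossBreakdown, {stride: grad array}, [offset grad arrays]).

    Setting ``focal_gamma`` > 0 switches the objectness term to a focal
    variant (off by default).
    """
    n_batch = raw_outputs[next(iter(raw_outputs))].shape[1]
    grads = {s: np.zeros_like(o) for s, o in raw_outputs.items()}

    # assemble targets
    per_image = [assign_targets(image_size, anns) for anns in batch_annotations]

    total_obj_loss = 0.0
    total_obj_count = 0
    cls_losses, det_losses = [], []
    for stride, out in raw_outputs.items():
        _, n, h, w = out.shape
        obj_t = np.stack([per_image[i][stride][0] for i in range(n)])  # (N,h,w)
        cls_t = np.stack([per_image[i][stride][1] for i in range(n)])
        box_t = np.stack([per_image[i][stride][2] for i in range(n)])

        z_obj = out[4].astype(np.float64)  # (N,h,w)
        p_obj = 1.0 / (1.0 + np.exp(-z_obj))
        p_clip = np.clip(p_obj, _LOG_GUARD, 1 - _LOG_GUARD)
        if focal_gamma > 0:
            pt = np.where(obj_t > 0, p_clip, 1 - p_clip)
            total_obj_loss += float((-((1 - pt) ** focal_gamma) * np.log(pt)).sum())
            dl_dpt = (focal_gamma * (1 - pt) ** (focal_gamma - 1) * np.log(pt)
                      - (1 - pt) ** focal_gamma / pt)
            dpt_dz = np.where(obj_t > 0, 1.0, -1.0) * p_obj * (1 - p_obj)
            grad_obj = dl_dpt * dpt_dz
        else:
            total_obj_loss += float(
                (-(obj_t * np.log(p_clip)
                   + (1 - obj_t) * np.log(1 - p_clip))).sum())
            grad_obj = p_obj - obj_t
        total_obj_count += z_obj.size
        grads[stride][4] = grad_obj  # normalized later

        pos = obj_t > 0
        if not pos.any():
            continue
        pn, py, px = np.nonzero(pos)

        # classification at positive locations
        logits = out[5:, pn, py, px].astype(np.float64).T  # (P, nc)
        logits -= logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        tgt = cls_t[pn, py, px]
        cls_losses.append(-np.log(np.maximum(probs[np.arange(len(tgt)), tgt],
                                             _LOG_GUARD)))
        gcls = probs.copy()
        gcls[np.arange(len(tgt)), tgt] -= 1.0
        grads[stride][5:, pn, py, px] = gcls.T  # normalized later

        # localization: decode distances and take CIoU against targets
        raw_box = out[:4, pn, py, px].astype(np.float64).T  # (P, 4) l,t,r,b
        dist = np.exp(np.clip(raw_box, -10, 6)) * stride
        ctr_x = (px + 0.5) * stride
        ctr_y = (py + 0.5) * stride
        pred = np.stack([ctr_x - dist[:, 0], ctr_y - dist[:, 1],
                         ctr_x + dist[:, 2], ctr_y + dist[:, 3]], axis=1)
        truth = box_t[pn, py, px]
        loss_vec, dpred = ciou_loss_grad(pred, truth)
        det_losses.append(loss_vec)
        # chain through the exp decoding: d corner/d raw = (-+) dist
        sign = np.array([-1.0, -1.0, 1.0, 1.0])
        graw = dpred * sign * dist
        grads[stride][:4, pn, py, px] = graw.T  # normalized later

    n_pos = sum(len(v) for v in cls_losses)
    l_obj = total_obj_loss / max(total_obj_count, 1)
    l_cls_only = (float(np.concatenate(cls_losses).mean()) if n_pos else 0.0)
    l_det = (float(np.concatenate(det_losses).mean()) if n_pos else 0.0)
    l_cls = l_cls_only + l_obj

    # apply normalizations and loss weights to the gradients
    for stride in grads:
        grads[stride][4] *= weights.lambda_cls / max(total_obj_count, 1)
        if n_pos:
            grads[stride][5:] *= weights.lambda_cls / n_pos
            grads[stride][:4] *= weights.lambda_det / n_pos

    # offset regularization over all deformable layers
    offset_grads = []
    if offset_fields:
        m_total = sum(f.size // 2 for f in offset_fields)
        sq = 0.0
        for f in offset_fields:
            sq += float((f.astype(np.float64) ** 2).sum())
            offset_grads.append(
                (2.0 * weights.lambda_reg / max(m_total, 1)) * f)
        l_reg = sq / max(m_total, 1)
    else:
        l_reg = 0.0

    return total_loss(l_reg, l_cls, l_det, weights), grads, offset_grads
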