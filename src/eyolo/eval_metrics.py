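"""Detection evaluation: IoU, matching, P/R/F1, AP/mAP, accuracy,
and the six-class confusion matrix.

Definitions (C_pos = true positives, M_pos = false positives,
M_neg = false negatives, C_neg = correctly ignored background):

    P  = C_pos / (C_pos + M_pos)          R = C_pos / (C_pos + M_neg)
    F1 = 2PR / (P + R)
    AP = area under the precision-recall curve (all-point by default,
         101-point COCO interpolation by flag)
    mAP = mean AP over classes;  the range variant averages over
          tau in {0.50, 0.55, ..., 0.95}
    A  = (C_pos + C_neg) / (C_pos + C_neg + M_pos + M_neg)

Detection has no natural true-negative count; C_neg here is the number
of prediction-grid locations that are negative in the ground truth and
score below the confidence threshold, which makes A resolution-dependent
(documented choice).

Matching is greedy and one-to-one, class-strict for P/R/F1/AP and
class-agnostic for the confusion matrix (which must be able to record
cross-class confusions).  Score ties break by input order; IoU ties by
first truth index.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from eyolo.smear_synth import CLASS_NAMES, NUM_CLASSES

RANGE_TAUS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (x1, y1, x2, y2) boxes."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    if ax2 <= ax1 or ay2 <= ay1 or bx2 <= bx1 or by2 <= by1:
        raise ValueError("degenerate box")
    ix = min(ax2, bx2) - max(ax1, bx1)
    iy = min(ay2, by2) - max(ay1, by1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


# Records: detections as (image_id, class_idx, score, box_xyxy),
# truths as (image_id, class_idx, box_xyxy).

@dataclasses.dataclass
class MatchResult:
    c_pos: int
    m_pos: int
    m_neg: int
    c_neg: int = 0
    pairs: list = dataclasses.field(default_factory=list)  # (det, truth, IoU)


def _sort_by_score(dets):
    order = sorted(range(len(dets)), key=lambda i: (-dets[i][2], i))
    return [dets[i] for i in order]


def match_detections(detections, truths, tau_iou: float = 0.5,
                     c_neg: int = 0) -> MatchResult:
    """Greedy one-to-one class-strict matching.

    Each detection (descending score) matches the unmatched same-class,
    same-image truth with highest IoU if that IoU >= tau_iou; otherwise it
    counts as a false positive.  Unmatched truths are false negatives.
    ``c_neg`` (background true negatives) is supplied by the evaluation
    pipeline, which knows the prediction-grid size.
    """
    dets = _sort_by_score(list(detections))
    matched = [False] * len(truths)
    pairs = []
    m_pos = 0
    for det in dets:
        img, cls, _score, box = det
        best_iou, best_j = 0.0, -1
        for j, (timg, tcls, tbox) in enumerate(truths):
            if matched[j] or timg != img or tcls != cls:
                continue
            v = iou(box, tbox)
            if v > best_iou:  # strict > keeps the first truth on ties
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= tau_iou:
            matched[best_j] = True
            pairs.append((det, truths[best_j], best_iou))
        else:
            m_pos += 1
    m_neg = matched.count(False)
    return MatchResult(c_pos=len(pairs), m_pos=m_pos, m_neg=m_neg,
                       c_neg=c_neg, pairs=pairs)


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """P, R and their harmonic mean, with the zero-denominator convention."""
    p = m.c_pos / (m.c_pos + m.m_pos) if m.c_pos + m.m_pos > 0 else 0.0
    r = m.c_pos / (m.c_pos + m.m_neg) if m.c_pos + m.m_neg > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def accuracy(m: MatchResult) -> float:
    """(C_pos + C_neg) / (C_pos + C_neg + M_pos + M_neg)."""
    denom = m.c_pos + m.c_neg + m.m_pos + m.m_neg
    if denom == 0:
        raise ValueError("accuracy undefined on an empty evaluation")
    return (m.c_pos + m.c_neg) / denom


def background_true_negatives(score_maps, target_maps,
                              conf_threshold: float = 0.25) -> int:
    """C_neg: grid locations that are truth-negative and score below threshold.

    ``score_maps`` / ``target_maps``: same-shaped per-scale arrays of decoded
    location scores and 0/1 objectness targets (any nesting of arrays).
    """
    total = 0
    for score, target in zip(score_maps, target_maps):
        score = np.asarray(score)
        target = np.asarray(target)
        total += int(((target == 0) & (score < conf_threshold)).sum())
    return total


# ---------------------------------------------------------------------------
# Average precision
# ---------------------------------------------------------------------------

def _pr_points(detections, truths, cls: int, tau_iou: float):
    """Cumulative (recall, precision) points for one class, globally ranked."""
    cls_truths = [t for t in truths if t[1] == cls]
    n_truth = len(cls_truths)
    dets = _sort_by_score([d for d in detections if d[1] == cls])
    matched = [False] * n_truth
    tps = np.zeros(len(dets), dtype=bool)
    for i, det in enumerate(dets):
        best_iou, best_j = 0.0, -1
        for j, (timg, _tcls, tbox) in enumerate(cls_truths):
            if matched[j] or timg != det[0]:
                continue
            v = iou(det[3], tbox)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= tau_iou:
            matched[best_j] = True
            tps[i] = True
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(~tps)
    recall = tp_cum / n_truth if n_truth else np.zeros(len(dets))
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    return recall, precision, n_truth


def average_precision(detections, truths, cls: int, tau_iou: float = 0.5,
                      method: str = "all_points") -> float:
    """Area under the precision envelope over recall for one class.

    ``method``: "all_points" (exact area, Pascal-style) or "coco101"
    (101-point interpolation).  Raises if the class has no ground truth.
    """
    recall, precision, n_truth = _pr_points(detections, truths, cls, tau_iou)
    if n_truth == 0:
        raise ValueError(f"AP undefined: no ground truth of class {cls}")
    if len(recall) == 0:
        return 0.0
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    # precision envelope (monotone non-increasing from the right)
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    if method == "coco101":
        grid = np.linspace(0, 1, 101)
        idx = np.searchsorted(mrec, grid, side="left")
        return float(mpre[np.minimum(idx, len(mpre) - 1)].mean())
    if method != "all_points":
        raise ValueError(f"unknown AP method {method!r}")
    changes = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(((mrec[changes + 1] - mrec[changes]) * mpre[changes + 1]).sum())


def map_at(detections, truths, tau_iou: float = 0.5,
           num_classes: int = NUM_CLASSES, method: str = "all_points") -> float:
    """Mean AP over the classes present in the ground truth."""
    if not truths:
        raise ValueError("mAP undefined on an empty truth set")
    present = sorted({t[1] for t in truths})
    missing = set(range(num_classes)) - set(present)
    if missing:
        warnings.warn(f"classes absent from ground truth excluded from mAP: "
                      f"{sorted(missing)}", RuntimeWarning, stacklevel=2)
    aps = [average_precision(detections, truths, c, tau_iou, method)
           for c in present]
    return float(np.mean(aps))


def map_range(detections, truths, num_classes: int = NUM_CLASSES,
              method: str = "coco101") -> float:
    """mAP averaged over IoU thresholds 0.50:0.05:0.95 (COCO protocol)."""
    return float(np.mean([map_at(detections, truths, t, num_classes, method)
                          for t in RANGE_TAUS]))


# ---------------------------------------------------------------------------
# Confusion matrix (class-agnostic matching)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConfusionMatrix:
    """Rows = ground-truth class, columns = predicted class; unmatched
    truths/predictions are tallied outside the matrix."""

    matrix: np.ndarray                 # (C, C) counts
    unmatched_truth: np.ndarray        # (C,)
    unmatched_pred: np.ndarray         # (C,)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.matrix, index=CLASS_NAMES, columns=CLASS_NAMES)


def confusion_matrix(detections, truths, tau_iou: float = 0.5,
                     num_classes: int = NUM_CLASSES) -> ConfusionMatrix:
    """Greedy class-agnostic IoU matching, then count (truth, predicted)."""
    mat = np.zeros((num_classes, num_classes), dtype=np.int64)
    un_truth = np.zeros(num_classes, dtype=np.int64)
    un_pred = np.zeros(num_classes, dtype=np.int64)
    matched = [False] * len(truths)
    for det in _sort_by_score(list(detections)):
        best_iou, best_j = 0.0, -1
        for j, (timg, _tcls, tbox) in enumerate(truths):
            if matched[j] or timg != det[0]:
                continue
            v = iou(det[3], tbox)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= tau_iou:
            matched[best_j] = True
            mat[truths[best_j][1], det[1]] += 1
        else:
            un_pred[det[1]] += 1
    for j, t in enumerate(truths):
        if not matched[j]:
            un_truth[t[1]] += 1
    return ConfusionMatrix(mat, un_truth, un_pred)


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MetricReport:
    """Per-class P/R/F1/AP plus mAP, accuracy, and mean matched IoU."""

    per_class: dict[str, dict[str, float]]
    map50: float
    map_range: float
    accuracy: float | None
    mean_iou: float
    per_tau_map: dict[float, float]

    def to_text(self) -> str:
        lines = [f"{'class':>6} {'P':>7} {'R':>7} {'F1':>7} {'AP@0.5':>7}"]
        for name, row in self.per_class.items():
            lines.append(f"{name:>6} {row['precision']:7.3f} {row['recall']:7.3f} "
                         f"{row['f1']:7.3f} {row['ap']:7.3f}")
        lines.append(f"mAP@0.5 = {self.map50:.4f}   "
                     f"mAP@0.5:0.95 = {self.map_range:.4f}")
        if self.accuracy is not None:
            lines.append(f"accuracy = {self.accuracy:.4f}")
        lines.append(f"mean matched IoU = {self.mean_iou:.4f}")
        return "\n".join(lines)


def evaluate_detections(detections, truths, tau_iou: float = 0.5,
                        c_neg: int = 0,
                        num_classes: int = NUM_CLASSES) -> MetricReport:
    """Full metric suite over ranked detections and ground truths."""
    per_class = {}
    present = sorted({t[1] for t in truths})
    for cls in present:
        cls_dets = [d for d in detections if d[1] == cls]
        cls_truths = [t for t in truths if t[1] == cls]
        m = match_detections(cls_dets, cls_truths, tau_iou)
        p, r, f1 = precision_recall_f1(m)
        per_class[CLASS_NAMES[cls]] = {
            "precision": p, "recall": r, "f1": f1,
            "ap": average_precision(detections, truths, cls, tau_iou)}
    overall = match_detections(detections, truths, tau_iou, c_neg=c_neg)
    mean_iou = (float(np.mean([v for _, _, v in overall.pairs]))
                if overall.pairs else 0.0)
    acc = accuracy(overall) if (overall.c_pos + overall.c_neg
                                + overall.m_pos + overall.m_neg) else None
    per_tau = {float(t): map_at(detections, truths, float(t), num_classes)
               for t in RANGE_TAUS}
    return MetricReport(
        per_class=per_class,
        map50=map_at(detections, truths, tau_iou, num_classes),
        map_range=float(np.mean(list(per_tau.values()))),
        accuracy=acc,
        mean_iou=mean_iou,
        per_tau_map=per_tau)
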