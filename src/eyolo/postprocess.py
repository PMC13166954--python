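"""Decode raw head outputs into detections, NMS, overlays, and the
plain-text diagnostic summary.

A detection carries the class-confidence vector p_t (softmax over the six
class logits), the decoded pixel box b_t, and a ranking score defined as
objectness x max class probability.  Non-maximum suppression is greedy
and class-wise: a box is kept iff its IoU with every already-kept,
higher-scored box of the same class stays below tau_IoU.  Overlays draw
abnormal classes (ARBC/AWBC/APL) in red and normal classes in green.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from PIL import Image, ImageDraw

from eyolo.smear_synth import ABNORMAL_CLASSES, CLASS_NAMES, CellClass

DEFAULT_CONF_THRESHOLD = 0.25
DEFAULT_NMS_IOU = 0.5


@dataclasses.dataclass(frozen=True)
class Detection:
    """One predicted cell: pixel corner box, class-confidence vector, score."""

    box: tuple[float, float, float, float]  # (x1, y1, x2, y2) pixels
    probs: tuple[float, ...]                # length-6 class confidences
    objectness: float

    @property
    def cell_class(self) -> CellClass:
        return CellClass(int(np.argmax(self.probs)))

    @property
    def score(self) -> float:
        return float(self.objectness * max(self.probs))

    @property
    def center_size(self) -> tuple[float, float, float, float]:
        x1, y1, x2, y2 = self.box
        return ((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)


@dataclasses.dataclass
class DetectionSet:
    """Detections for one image, sorted by descending score after NMS."""

    detections: list[Detection]
    image_size: tuple[int, int] | None = None  # (H, W)

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)


def decode(raw_outputs: dict[int, np.ndarray], image_size: tuple[int, int],
           confidence_threshold: float = DEFAULT_CONF_THRESHOLD
           ) -> DetectionSet:
    """Decode one image's per-scale raw outputs into candidate detections.

    ``raw_outputs``: {stride: (4 + 1 + nc, h, w)} with box log-distances
    (l, t, r, b), an objectness logit, and class logits.  Box distances
    convert as exp(raw) * stride around each location centre; class
    probabilities are a softmax over the class logits; candidates whose
    score falls below ``confidence_threshold`` are discarded and boxes are
    clipped to the image.
    """
    H, W = image_size
    candidates = []
    for stride, out in raw_outputs.items():
        if out.ndim == 4:
            if out.shape[1] != 1:
                raise ValueError("decode expects single-image outputs")
            out = out[:, 0]
        ch, h, w = out.shape
        if h * stride != H or w * stride != W:
            raise ValueError(
                f"scale {stride} grid {h}x{w} inconsistent with image {H}x{W}")
        obj = 1.0 / (1.0 + np.exp(-out[4].astype(np.float64)))
        logits = out[5:].astype(np.float64)
        logits -= logits.max(axis=0, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=0, keepdims=True)
        score = obj * probs.max(axis=0)
        keep = score >= confidence_threshold
        if not keep.any():
            continue
        py, px = np.nonzero(keep)
        dist = np.exp(np.clip(out[:4, py, px].astype(np.float64), -10, 6)) * stride
        cx = (px + 0.5) * stride
        cy = (py + 0.5) * stride
        x1 = np.clip(cx - dist[0], 0, W)
        y1 = np.clip(cy - dist[1], 0, H)
        x2 = np.clip(cx + dist[2], 0, W)
        y2 = np.clip(cy + dist[3], 0, H)
        for i in range(len(py)):
            if x2[i] <= x1[i] or y2[i] <= y1[i]:
                continue
            candidates.append(Detection(
                (float(x1[i]), float(y1[i]), float(x2[i]), float(y2[i])),
                tuple(float(v) for v in probs[:, py[i], px[i]]),
                float(obj[py[i], px[i]])))
    candidates.sort(key=lambda d: -d.score)
    return DetectionSet(candidates, image_size)


def _iou_xyxy(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter <= 0:
        return 0.0
    union = ((a[2] - a[0]) * (a[3] - a[1])
             + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return inter / union


def nms(candidates: DetectionSet, tau_iou: float = DEFAULT_NMS_IOU
        ) -> DetectionSet:
    """Greedy class-wise suppression at IoU threshold ``tau_iou``."""
    if not 0.0 < tau_iou <= 1.0:
        raise ValueError("tau_iou must lie in (0, 1]")
    ordered = sorted(candidates.detections, key=lambda d: -d.score)
    kept: list[Detection] = []
    for det in ordered:
        suppressed = any(
            k.cell_class == det.cell_class
            and _iou_xyxy(k.box, det.box) >= tau_iou
            for k in kept)
        if not suppressed:
            kept.append(det)
    return DetectionSet(kept, candidates.image_size)


# ---------------------------------------------------------------------------
# Rendering and reporting
# ---------------------------------------------------------------------------

_GREEN = (40, 180, 60)
_RED = (220, 40, 40)


def render_overlay(image: np.ndarray, detections: DetectionSet) -> Image.Image:
    """Draw class-colored boxes (red = abnormal, green = normal) with
    the class name and the confidence to two decimals."""
    img = Image.fromarray(np.asarray(image)).convert("RGB")
    draw = ImageDraw.Draw(img)
    for det in detections:
        color = _RED if det.cell_class.is_abnormal else _GREEN
        x1, y1, x2, y2 = det.box
        draw.rectangle([x1, y1, x2, y2], outline=color, width=1)
        draw.text((x1 + 1, max(0, y1 - 10)),
                  f"{det.cell_class.name} {det.score:.2f}", fill=color)
    return img


@dataclasses.dataclass(frozen=True)
class ReportSummary:
    """Per-image diagnostic counts with a fixed, non-clinical suggestion."""

    per_class: dict[str, int]
    normal_total: int
    abnormal_total: int
    dominant_abnormality: str  # class name or "none"
    suggestion: str

    def to_text(self) -> str:
        lines = ["Blood smear analysis summary", "-" * 30]
        for name in CLASS_NAMES:
            lines.append(f"{name:>5}: {self.per_class[name]}")
        lines.append(f"normal cells:   {self.normal_total}")
        lines.append(f"abnormal cells: {self.abnormal_total}")
        lines.append(f"dominant abnormality: {self.dominant_abnormality}")
        lines.append(f"suggestion: {self.suggestion}")
        return "\n".join(lines)


def generate_report(detections: DetectionSet) -> ReportSummary:
    """Count detections per class and name the modal abnormal class.

    Ties between abnormal classes break by fixed class order
    (ARBC < AWBC < APL); with no abnormal detections the dominant
    abnormality is "none".
    """
    counts = {name: 0 for name in CLASS_NAMES}
    for det in detections:
        counts[det.cell_class.name] += 1
    normal = sum(counts[c.name] for c in CellClass if not c.is_abnormal)
    abnormal = sum(counts[c.name] for c in ABNORMAL_CLASSES)
    dominant = "none"
    best = 0
    for c in ABNORMAL_CLASSES:  # fixed order implements the tie-break
        if counts[c.name] > best:
            best = counts[c.name]
            dominant = c.name
    if dominant == "none":
        suggestion = "no abnormal cells flagged; routine review"
    else:
        suggestion = f"review recommended: {dominant} (not a diagnosis)"
    return ReportSummary(counts, normal, abnormal, dominant, suggestion)


# ---------------------------------------------------------------------------
# Export formats
# ---------------------------------------------------------------------------

def detections_to_yolo_lines(detections: DetectionSet,
                             image_size: tuple[int, int]) -> list[str]:
    """YOLO-style label lines with an appended confidence column."""
    H, W = image_size
    lines = []
    for det in detections:
        cx, cy, w, h = det.center_size
        lines.append(f"{int(det.cell_class)} {cx / W:.6f} {cy / H:.6f} "
                     f"{w / W:.6f} {h / H:.6f} {det.score:.4f}")
    return lines


def detections_to_jsonl(detections: DetectionSet, image_id: str) -> list[str]:
    return [json.dumps({
        "image": image_id,
        "class": det.cell_class.name,
        "box": [round(v, 2) for v in det.box],
        "score": round(det.score, 4),
    }) for det in detections]
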