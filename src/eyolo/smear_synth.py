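"""Synthetic peripheral-blood-smear scenes with YOLO-format annotations.

Scenes emulate the statistical structure of a clinician-annotated smear
corpus: dense near-circular red cells, sparser large nucleated white
cells, small platelet specks, and three abnormal variants (elongated
elliptocyte-like ARBC, enlarged atypical AWBC with an irregular nucleus,
giant APL).  Cells are flat-shaded ellipses with bounded stain jitter and
additive Gaussian noise -- enough texture for a detector to learn from,
cheap enough to generate thousands of scenes on a CPU.

Per-image cell counts are Poisson with configurable per-class means whose
defaults reproduce the reference corpus density (normal mean ~7.9,
abnormal ~3.4 annotations per image, overall capped at 38).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image


class CellClass(enum.IntEnum):
    """The six detection classes, in canonical label-file index order."""

    RBC = 0
    WBC = 1
    PL = 2
    ARBC = 3
    AWBC = 4
    APL = 5

    @property
    def is_abnormal(self) -> bool:
        return self in (CellClass.ARBC, CellClass.AWBC, CellClass.APL)


CLASS_NAMES = tuple(c.name for c in CellClass)
NORMAL_CLASSES = (CellClass.RBC, CellClass.WBC, CellClass.PL)
ABNORMAL_CLASSES = (CellClass.ARBC, CellClass.AWBC, CellClass.APL)
NUM_CLASSES = 6


@dataclasses.dataclass(frozen=True)
class Annotation:
    """One ground-truth box: class plus (cx, cy, w, h) normalized to [0, 1]."""

    cell_class: CellClass
    box: tuple[float, float, float, float]

    def __post_init__(self):
        cx, cy, w, h = self.box
        if not (w > 0 and h > 0):
            raise ValueError(f"annotation box must have positive size, got {self.box}")
        if not (0.0 <= cx - w / 2 + 1e-9 and cx + w / 2 <= 1.0 + 1e-9
                and 0.0 <= cy - h / 2 + 1e-9 and cy + h / 2 <= 1.0 + 1e-9):
            raise ValueError(f"annotation box outside [0,1]^2: {self.box}")

    def to_pixels(self, width: int, height: int) -> tuple[float, float, float, float]:
        """Corner box (x1, y1, x2, y2) in pixel units."""
        cx, cy, w, h = self.box
        return ((cx - w / 2) * width, (cy - h / 2) * height,
                (cx + w / 2) * width, (cy + h / 2) * height)


# Default per-class Poisson means.  The normal/abnormal group means (7.9 and
# 3.4 annotations per image) are split across classes proportionally to the
# reference corpus' per-class annotation totals.
DEFAULT_CLASS_MEANS: dict[str, float] = {
    "RBC": 5.60,
    "WBC": 0.98,
    "PL": 1.32,
    "ARBC": 1.94,
    "AWBC": 0.89,
    "APL": 0.57,
}


@dataclasses.dataclass(frozen=True)
class SmearSceneConfig:
    """Generator configuration; (seed, config) fully determines every byte.

    ``class_means`` are per-image Poisson means per class; ``max_total``
    truncates the total count per image (the reference corpus maximum is 38).
    ``overlap_fraction`` is the probability that a cell is allowed to
    partially overlap an already-placed neighbour.  ``stain_jitter`` bounds
    the per-image multiplicative hue/brightness perturbation.
    """

    image_size: tuple[int, int] = (256, 256)  # (height, width)
    class_means: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEANS))
    overlap_fraction: float = 0.3
    stain_jitter: float = 0.05
    noise_sigma: float = 0.02
    max_total: int = 38
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ValueError("image_size too small to place a single cell")
        for name, m in self.class_means.items():
            if name not in CLASS_NAMES:
                raise ValueError(f"unknown cell class {name!r}")
            if m < 0:
                raise ValueError(f"mean count for {name} must be >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.stain_jitter < 0 or self.noise_sigma < 0:
            raise ValueError("jitter/noise amplitudes must be >= 0")


# ---------------------------------------------------------------------------
# Cell morphology: sizes as fractions of min(H, W), flat-shaded colours.
# Abnormal variants differ by a controlled morphology delta: ARBC by
# eccentricity, AWBC by size + irregular nucleus, APL by speck size.
# ---------------------------------------------------------------------------

_BACKGROUND = np.array([0.95, 0.93, 0.95])

_GEOMETRY = {
    # radius_mean, radius_sd, aspect_lo, aspect_hi  (radius = semi-major axis)
    CellClass.RBC: (0.055, 0.004, 0.88, 1.00),
    CellClass.WBC: (0.095, 0.006, 0.85, 1.00),
    CellClass.PL: (0.036, 0.003, 0.80, 1.00),
    CellClass.ARBC: (0.060, 0.004, 0.38, 0.55),   # elliptocyte-like
    CellClass.AWBC: (0.130, 0.009, 0.80, 0.95),   # enlarged atypical
    CellClass.APL: (0.068, 0.005, 0.70, 0.90),    # giant platelet
}

_COLORS = {
    CellClass.RBC: np.array([0.90, 0.55, 0.55]),
    CellClass.ARBC: np.array([0.88, 0.52, 0.52]),
    CellClass.WBC: np.array([0.80, 0.72, 0.90]),
    CellClass.AWBC: np.array([0.74, 0.64, 0.88]),
    CellClass.PL: np.array([0.58, 0.42, 0.72]),
    CellClass.APL: np.array([0.55, 0.38, 0.70]),
}
_NUCLEUS_COLOR = np.array([0.38, 0.24, 0.55])


def _ellipse_mask(yy, xx, cx, cy, a, b, angle):
    ca, sa = math.cos(angle), math.sin(angle)
    xr = (xx - cx) * ca + (yy - cy) * sa
    yr = -(xx - cx) * sa + (yy - cy) * ca
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _ellipse_aabb(cx, cy, a, b, angle):
    """Tight axis-aligned half-extents of a rotated ellipse."""
    ca, sa = math.cos(angle), math.sin(angle)
    ex = math.sqrt((a * ca) ** 2 + (b * sa) ** 2)
    ey = math.sqrt((a * sa) ** 2 + (b * ca) ** 2)
    return cx - ex, cy - ey, cx + ex, cy + ey


def _draw_cell(canvas, yy, xx, cls, cx, cy, a, b, angle, rng):
    jitter = 1.0 + 0.06 * (rng.random(3) - 0.5)
    body = _ellipse_mask(yy, xx, cx, cy, a, b, angle)
    canvas[body] = np.clip(_COLORS[cls] * jitter, 0, 1)
    if cls == CellClass.RBC or cls == CellClass.ARBC:
        # central pallor
        pallor = _ellipse_mask(yy, xx, cx, cy, 0.45 * a, 0.45 * b, angle)
        canvas[pallor] = np.clip(_COLORS[cls] * jitter * 1.12, 0, 1)
    elif cls == CellClass.WBC:
        nuc = _ellipse_mask(yy, xx, cx, cy, 0.55 * a, 0.55 * b,
                            angle + rng.uniform(-0.5, 0.5))
        canvas[nuc] = np.clip(_NUCLEUS_COLOR * jitter, 0, 1)
    elif cls == CellClass.AWBC:
        # irregular multi-lobed nucleus: three overlapping dark blobs
        for _ in range(3):
            dx = rng.uniform(-0.3, 0.3) * a
            dy = rng.uniform(-0.3, 0.3) * b
            lobe = _ellipse_mask(yy, xx, cx + dx, cy + dy,
                                 0.38 * a, 0.38 * b, rng.uniform(0, math.pi))
            canvas[lobe] = np.clip(_NUCLEUS_COLOR * jitter * 0.9, 0, 1)


def _sample_counts(config: SmearSceneConfig, rng) -> dict[CellClass, int]:
    counts = {}
    for cls in CellClass:
        mean = config.class_means.get(cls.name, 0.0)
        counts[cls] = int(rng.poisson(mean)) if mean > 0 else 0
    # truncate total at the configured maximum, trimming the most numerous
    # class first (ties broken by class order) -- deterministic
    while sum(counts.values()) > config.max_total:
        worst = max(CellClass, key=lambda c: (counts[c], -int(c)))
        counts[worst] -= 1
    return counts


def generate_scene(config: SmearSceneConfig, scene_index: int
                   ) -> tuple[np.ndarray, list[Annotation]]:
    """Render one synthetic smear scene.

    Returns an (H, W, 3) uint8 image and one tightly-enclosing
    :class:`Annotation` per drawn cell.  Deterministic: the pair
    (config.seed, scene_index) fixes every generated byte.
    """
    H, W = config.image_size
    S = min(H, W)
    rng = np.random.default_rng([config.seed, scene_index])
    counts = _sample_counts(config, rng)

    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    canvas = np.ones((H, W, 3), dtype=np.float64) * _BACKGROUND

    # place large cells first so small specks stay visible on top
    order = [CellClass.AWBC, CellClass.WBC, CellClass.APL,
             CellClass.ARBC, CellClass.RBC, CellClass.PL]
    placed: list[tuple[float, float, float]] = []  # (cx, cy, effective radius)
    annotations: list[Annotation] = []
    for cls in order:
        rm, rs, alo, ahi = _GEOMETRY[cls]
        for _ in range(counts[cls]):
            a = max(2.0, rng.normal(rm * S, rs * S))
            aspect = rng.uniform(alo, ahi)
            b = max(1.5, a * aspect)
            angle = rng.uniform(0.0, math.pi)
            allow_overlap = rng.random() < config.overlap_fraction
            reff = 0.5 * (a + b)
            for _try in range(40):
                cx = rng.uniform(a + 1, W - a - 1) if W > 2 * a + 2 else W / 2
                cy = rng.uniform(a + 1, H - a - 1) if H > 2 * a + 2 else H / 2
                worst = 0.0
                for (px, py, pr) in placed:
                    d = math.hypot(cx - px, cy - py)
                    worst = max(worst, 1.0 - d / (reff + pr))
                limit = 0.45 if allow_overlap else 0.05
                if worst < limit:
                    break
            else:
                continue  # could not place this cell; skip it
            placed.append((cx, cy, reff))
            _draw_cell(canvas, yy, xx, cls, cx, cy, a, b, angle, rng)
            x1, y1, x2, y2 = _ellipse_aabb(cx, cy, a, b, angle)
            x1, y1 = max(0.0, x1), max(0.0, y1)
            x2, y2 = min(float(W), x2), min(float(H), y2)
            annotations.append(Annotation(
                cls, ((x1 + x2) / 2 / W, (y1 + y2) / 2 / H,
                      (x2 - x1) / W, (y2 - y1) / H)))

    # bounded stain jitter (per-image channel gain + brightness) and noise
    gain = 1.0 + config.stain_jitter * (rng.random(3) * 2 - 1)
    shift = 0.5 * config.stain_jitter * (rng.random() * 2 - 1)
    canvas = canvas * gain + shift
    if config.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, config.noise_sigma, canvas.shape)
    image = (np.clip(canvas, 0.0, 1.0) * 255).round().astype(np.uint8)
    return image, annotations


def generate_scenes(config: SmearSceneConfig, n_scenes: int
                    ) -> list[tuple[np.ndarray, list[Annotation]]]:
    """Generate ``n_scenes`` scenes with indices 0..n-1."""
    return [generate_scene(config, i) for i in range(n_scenes)]


# ---------------------------------------------------------------------------
# Density summary (per-image annotation counts)
# ---------------------------------------------------------------------------

def density_summary(datasets: Sequence[tuple[np.ndarray, list[Annotation]]]
                    ) -> pd.DataFrame:
    """Per-image count statistics for normal / abnormal / overall groups.

    Returns a DataFrame indexed by group with columns
    ``mean, std, min, max, median`` (population std).
    """
    if len(datasets) == 0:
        raise ValueError("density_summary requires at least one scene")
    normal = np.array([sum(1 for a in anns if not a.cell_class.is_abnormal)
                       for _, anns in datasets], dtype=float)
    abnormal = np.array([sum(1 for a in anns if a.cell_class.is_abnormal)
                         for _, anns in datasets], dtype=float)
    overall = normal + abnormal
    rows = {}
    for name, x in (("normal", normal), ("abnormal", abnormal),
                    ("overall", overall)):
        rows[name] = {"mean": x.mean(), "std": x.std(),
                      "min": x.min(), "max": x.max(),
                      "median": float(np.median(x))}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["mean", "std", "min", "max", "median"])


# ---------------------------------------------------------------------------
# YOLO-format dataset I/O
# ---------------------------------------------------------------------------

SPLIT_NAMES = ("train", "val", "test")


class YoloFormatError(ValueError):
    """Raised for malformed YOLO label files (names file and line)."""


def split_sizes(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """Floor allocation per split; the remainder goes to train."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    if any(r < 0 for r in ratios):
        raise ValueError("split ratios must be >= 0")
    n_train = int(math.floor(ratios[0] * n))
    n_val = int(math.floor(ratios[1] * n))
    n_test = int(math.floor(ratios[2] * n))
    n_train += n - (n_train + n_val + n_test)
    return n_train, n_val, n_test


def write_yolo_dataset(scenes: Sequence[tuple[np.ndarray, list[Annotation]]],
                       split_ratios: tuple[float, float, float],
                       root_path: str | Path,
                       *,
                       seed: int = 0,
                       config: SmearSceneConfig | None = None,
                       batch_size: int = 10) -> Path:
    """Write scenes to ``root/images/<split>/`` and ``root/labels/<split>/``.

    Splits by a deterministic seed-driven shuffle with floor-allocated sizes
    (remainder to train; default ratios 0.70/0.15/0.15).  A ``manifest.yaml``
    records the seed, generator config, per-scene acquisition-batch id and
    the exact split assignment.  No scene appears in two splits.
    """
    root = Path(root_path)
    n = len(scenes)
    n_train, n_val, n_test = split_sizes(n, tuple(split_ratios))
    order = np.random.default_rng(seed).permutation(n)
    assignment = {
        "train": sorted(int(i) for i in order[:n_train]),
        "val": sorted(int(i) for i in order[n_train:n_train + n_val]),
        "test": sorted(int(i) for i in order[n_train + n_val:]),
    }
    for split, indices in assignment.items():
        img_dir = root / "images" / split
        lbl_dir = root / "labels" / split
        img_dir.mkdir(parents=True, exist_ok=True)
        lbl_dir.mkdir(parents=True, exist_ok=True)
        for i in indices:
            image, anns = scenes[i]
            name = f"scene_{i:05d}"
            Image.fromarray(image).save(img_dir / f"{name}.png")
            lines = [f"{int(a.cell_class)} "
                     f"{a.box[0]:.6f} {a.box[1]:.6f} {a.box[2]:.6f} {a.box[3]:.6f}"
                     for a in anns]
            (lbl_dir / f"{name}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))
    manifest = {
        "seed": int(seed),
        "split_ratios": [float(r) for r in split_ratios],
        "splits": assignment,
        "batch_ids": {int(i): int(i) // batch_size for i in range(n)},
        "class_names": list(CLASS_NAMES),
    }
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["image_size"] = list(cfg["image_size"])
        manifest["generator_config"] = cfg
    with open(root / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return root


def _parse_label_file(path: Path) -> list[Annotation]:
    anns = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 5:
            raise YoloFormatError(
                f"{path}:{lineno}: expected 5 fields 'class cx cy w h', "
                f"got {len(fields)}")
        try:
            idx = int(fields[0])
            cx, cy, w, h = (float(v) for v in fields[1:])
        except ValueError as exc:
            raise YoloFormatError(f"{path}:{lineno}: {exc}") from exc
        if not 0 <= idx < NUM_CLASSES:
            raise YoloFormatError(
                f"{path}:{lineno}: class index {idx} out of range [0, {NUM_CLASSES})")
        try:
            anns.append(Annotation(CellClass(idx), (cx, cy, w, h)))
        except ValueError as exc:
            raise YoloFormatError(f"{path}:{lineno}: {exc}") from exc
    return anns


def read_yolo_dataset(root_path: str | Path
                      ) -> dict[str, list[tuple[np.ndarray, list[Annotation]]]]:
    """Read a YOLO-format dataset directory written by :func:`write_yolo_dataset`.

    Also accepts externally prepared data with the same images/labels layout.
    Returns ``{split: [(image, annotations), ...]}`` for every split present.
    """
    root = Path(root_path)
    if not (root / "images").is_dir():
        raise FileNotFoundError(f"no images/ directory under {root}")
    out: dict[str, list[tuple[np.ndarray, list[Annotation]]]] = {}
    for split_dir in sorted((root / "images").iterdir()):
        if not split_dir.is_dir():
            continue
        split = split_dir.name
        items = []
        for img_path in sorted(split_dir.glob("*")):
            if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            image = np.asarray(Image.open(img_path).convert("RGB"))
            lbl_path = root / "labels" / split / (img_path.stem + ".txt")
            anns = _parse_label_file(lbl_path) if lbl_path.exists() else []
            items.append((image, anns))
        out[split] = items
    return out
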