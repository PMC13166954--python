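"""Channel normalization and bounded affine augmentation.

Images are standardized per channel with the mean/std of the *training*
pixels only.  Training-time augmentation is restricted to mild affine
transforms -- rotation in [-15, 15] degrees, isotropic scale in
[0.9, 1.1], translation within 10% of the image extent -- applied about
the image centre in the order rotate -> scale -> translate.  Colour
jitter, elastic deformation and intensity distortion are deliberately
never applied: they would corrupt diagnostically relevant morphology.

Bounding boxes are transformed by mapping their four corners and taking
the axis-aligned enclosure; boxes whose clipped area drops below 20% of
the original are dropped as degenerate slivers.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import ndimage

from eyolo.smear_synth import Annotation

_EPS = 1e-8

ROTATION_RANGE = (-15.0, 15.0)
SCALE_RANGE = (0.9, 1.1)
TRANSLATION_FRACTION = 0.1
AREA_KEEP_FRACTION = 0.2


@dataclasses.dataclass(frozen=True)
class NormalizationStats:
    """Per-channel mean and standard deviation of the training pixels."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=np.float64))
        if np.any(self.std <= 0):
            raise ValueError("std must be > 0 (epsilon-guarded upstream)")


@dataclasses.dataclass(frozen=True)
class AffineParams:
    """Rotation (degrees), isotropic scale, translation (pixels), extent R."""

    theta: float
    scale: float
    tx: float
    ty: float
    extent: float

    def __post_init__(self):
        if not ROTATION_RANGE[0] <= self.theta <= ROTATION_RANGE[1]:
            raise ValueError(f"rotation {self.theta} outside {ROTATION_RANGE}")
        if not SCALE_RANGE[0] <= self.scale <= SCALE_RANGE[1]:
            raise ValueError(f"scale {self.scale} outside {SCALE_RANGE}")
        bound = TRANSLATION_FRACTION * self.extent + 1e-12
        if abs(self.tx) > bound or abs(self.ty) > bound:
            raise ValueError(
                f"translation ({self.tx}, {self.ty}) exceeds +-{bound:.3f}")


def compute_norm_stats(training_images) -> NormalizationStats:
    """Population mean/std per channel over every training pixel.

    Constant channels are sigma-clamped to 1e-8 with a warning.  Statistics
    must be computed on the training split only; validation/test images are
    normalized with these same values.
    """
    images = list(training_images)
    if not images:
        raise ValueError("compute_norm_stats requires at least one image")
    pixels = np.concatenate(
        [np.asarray(im, dtype=np.float64).reshape(-1, np.asarray(im).shape[-1])
         for im in images], axis=0)
    mean = pixels.mean(axis=0)
    std = pixels.std(axis=0)  # population std
    if np.any(std < _EPS):
        warnings.warn("constant channel encountered; std clamped to epsilon",
                      RuntimeWarning, stacklevel=2)
        std = np.maximum(std, _EPS)
    return NormalizationStats(mean, std)


def normalize(image, stats: NormalizationStats) -> np.ndarray:
    """(image - mu) / sigma, elementwise per channel."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape[-1] != stats.mean.shape[0]:
        raise ValueError(
            f"image has {image.shape[-1]} channels, stats have {stats.mean.shape[0]}")
    return (image - stats.mean) / stats.std


def sample_affine(rng: np.random.Generator, image_extent: float) -> AffineParams:
    """Draw augmentation parameters uniformly from their allowed ranges."""
    theta = rng.uniform(*ROTATION_RANGE)
    scale = rng.uniform(*SCALE_RANGE)
    bound = TRANSLATION_FRACTION * image_extent
    tx = rng.uniform(-bound, bound)
    ty = rng.uniform(-bound, bound)
    return AffineParams(theta, scale, tx, ty, image_extent)


def _forward_matrix(params: AffineParams, height: int, width: int) -> np.ndarray:
    """3x3 pixel-coordinate map (x, y): rotate -> scale -> translate about centre."""
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    th = math.radians(params.theta)
    c, s = math.cos(th), math.sin(th)
    rs = params.scale * np.array([[c, -s], [s, c]])
    t = np.array([params.tx + cx, params.ty + cy]) - rs @ np.array([cx, cy])
    m = np.eye(3)
    m[:2, :2] = rs
    m[:2, 2] = t
    return m


def apply_affine(image: np.ndarray, annotations, params: AffineParams
                 ) -> tuple[np.ndarray, list[Annotation]]:
    """Warp image and boxes consistently.

    The image is resampled bilinearly with zero padding.  Each box is
    transformed by mapping its four corners through the same matrix and
    taking the axis-aligned enclosure, clipped to the image; boxes whose
    clipped area falls below 20% of the original are dropped.
    """
    image = np.asarray(image, dtype=np.float64)
    H, W = image.shape[:2]
    m = _forward_matrix(params, H, W)

    if (params.theta, params.scale, params.tx, params.ty) == (0.0, 1.0, 0.0, 0.0):
        warped = image.copy()
    else:
        inv = np.linalg.inv(m)
        # ndimage uses (row, col) order; swap the (x, y) matrix accordingly
        swap = np.array([[0, 1], [1, 0]])
        mat = swap @ inv[:2, :2] @ swap
        off = inv[:2, 2][::-1]
        if image.ndim == 2:
            warped = ndimage.affine_transform(image, mat, offset=off, order=1,
                                              mode="constant", cval=0.0)
        else:
            warped = np.stack(
                [ndimage.affine_transform(image[..., c], mat, offset=off,
                                          order=1, mode="constant", cval=0.0)
                 for c in range(image.shape[-1])], axis=-1)

    out_anns: list[Annotation] = []
    for ann in annotations:
        x1, y1, x2, y2 = ann.to_pixels(W, H)
        corners = np.array([[x1, y1, 1], [x2, y1, 1], [x1, y2, 1], [x2, y2, 1]]).T
        tx_, ty_ = (m @ corners)[:2]
        nx1, ny1, nx2, ny2 = tx_.min(), ty_.min(), tx_.max(), ty_.max()
        area0 = (nx2 - nx1) * (ny2 - ny1)
        cx1, cy1 = max(0.0, nx1), max(0.0, ny1)
        cx2, cy2 = min(float(W), nx2), min(float(H), ny2)
        if cx2 <= cx1 or cy2 <= cy1:
            continue
        if (cx2 - cx1) * (cy2 - cy1) < AREA_KEEP_FRACTION * area0:
            continue
        out_anns.append(Annotation(
            ann.cell_class,
            ((cx1 + cx2) / 2 / W, (cy1 + cy2) / 2 / H,
             (cx2 - cx1) / W, (cy2 - cy1) / H)))
    return warped, out_anns
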