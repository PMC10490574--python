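"""Texture features inside the bone mask.

Three first-order intensity statistics (mean as a marrow-fat/BMD surrogate,
population variance, skew), the box-counting fractal dimension of the
boundary pixel set, and four Haralick statistics of the gray-level
co-occurrence matrix (GLCM): contrast, correlation, energy, homogeneity.

GLCM settings: intensities quantized to 32 levels over the in-mask range,
symmetric normalized co-occurrence at distance 1 averaged over the four
angles {0, 45, 90, 135} degrees, pairs restricted to mask-internal pixels.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np
from scipy import stats as sp_stats
from skimage.feature import graycomatrix

from .errors import EmptyMaskError, ParameterError
from .image import PfbImage
from .segmentation import SegMask

GLCM_LEVELS = 32
GLCM_DISTANCE = 1
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
#: Box sizes for the box-counting dimension (powers of two).
BOX_SIZES = (2, 4, 8, 16, 32)

TEXTURE_FEATURE_NAMES = ["gray_mean", "gray_variance", "gray_skew"]
GLCM_FEATURE_NAMES = ["glcm_contrast", "glcm_correlation", "glcm_energy",
                      "glcm_homogeneity"]


@dataclasses.dataclass
class TextureFeatureSet:
    gray_mean: float
    gray_variance: float
    gray_skew: float
    fractal_dim: float
    glcm_contrast: float
    glcm_correlation: float
    glcm_energy: float
    glcm_homogeneity: float
    degenerate: bool = False


def _arr(image) -> np.ndarray:
    return image.pixels if isinstance(image, PfbImage) else np.asarray(image, float)


def _m(mask) -> np.ndarray:
    return mask.mask if isinstance(mask, SegMask) else np.asarray(mask, bool)


def gray_stats(image, mask) -> Tuple[float, float, float]:
    """(mean, population variance, skew) of in-mask intensities."""
    vals = _arr(image)[_m(mask)]
    if vals.size == 0:
        raise EmptyMaskError("gray_stats needs a nonempty mask")
    mean = float(vals.mean())
    var = float(vals.var())
    skew = 0.0 if var == 0 else float(sp_stats.skew(vals, bias=True))
    return mean, var, skew


def box_counts(points: np.ndarray, sizes=BOX_SIZES) -> Tuple[np.ndarray, np.ndarray]:
    """Number of occupied s x s boxes for each box size s.

    ``points`` is an (n, 2) array of pixel coordinates; boxes tile the
    point set's bounding box starting at its minimum corner.
    """
    pts = np.asarray(points)
    if pts.size == 0:
        raise EmptyMaskError("box counting needs a nonempty point set")
    origin = pts.min(axis=0)
    sizes = np.asarray(sizes)
    counts = []
    for s in sizes:
        cells = (pts - origin) // s
        counts.append(len(np.unique(cells, axis=0)))
    return sizes, np.asarray(counts)


def fractal_dimension(mask, *, sizes=BOX_SIZES, boundary: bool = True) -> float:
    """Box-counting dimension of the mask's boundary (or of the full mask).

    Returns the negative OLS slope of log N(s) versus log s. Box sizes
    larger than a quarter of the point-set extent are dropped; at least
    three usable scales are required.
    """
    if boundary and isinstance(mask, SegMask):
        pts = mask.boundary[:-1]
    else:
        pts = np.argwhere(_m(mask))
    if pts.size == 0:
        raise EmptyMaskError("fractal dimension of an empty set")
    extent = (pts.max(axis=0) - pts.min(axis=0) + 1).max()
    usable = [s for s in sizes if s <= max(extent // 4, 2)]
    if len(usable) < 3:
        raise ParameterError(
            f"fewer than 3 usable box sizes for extent {extent} (got {usable})")
    s, n = box_counts(pts, usable)
    slope = np.polyfit(np.log(s), np.log(n), 1)[0]
    return float(-slope)


def glcm_matrix(image, mask, *, levels: int = GLCM_LEVELS,
                distance: int = GLCM_DISTANCE,
                angles=GLCM_ANGLES) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix averaged over angles.

    Intensities are quantized to ``levels`` bins over the in-mask range;
    out-of-mask pixels are excluded from every pair via a sentinel level.
    """
    arr, m = _arr(image), _m(mask)
    if not m.any():
        raise EmptyMaskError("GLCM needs a nonempty mask")
    vals = arr[m]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.clip(((arr - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    else:
        q = np.zeros_like(arr, dtype=int)
    q = np.where(m, q, levels)  # sentinel level for background
    glcm = graycomatrix(q.astype(np.uint8), distances=[distance],
                        angles=list(angles), levels=levels + 1, symmetric=True,
                        normed=False)
    # drop pairs touching the background sentinel, average angles, normalize
    sub = glcm[:levels, :levels, 0, :].astype(float)
    p = sub.mean(axis=2)
    total = p.sum()
    if total == 0:
        raise EmptyMaskError("no mask-internal pixel pairs for the GLCM")
    return p / total


def glcm_features(image, mask, **kwargs) -> Tuple[float, float, float, float]:
    """(contrast, correlation, energy, homogeneity) by the Haralick formulas."""
    arr, m = _arr(image), _m(mask)
    vals = arr[m] if m.any() else np.array([])
    if vals.size == 0:
        raise EmptyMaskError("GLCM needs a nonempty mask")
    if np.ptp(vals) == 0:  # constant region: single co-occurrence cell
        return 0.0, 1.0, 1.0, 1.0

    p = glcm_matrix(image, mask, **kwargs)
    n = p.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    contrast = float((p * (i - j) ** 2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    energy = float((p ** 2).sum())
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    var_i = float((p * (i - mu_i) ** 2).sum())
    var_j = float((p * (j - mu_j) ** 2).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 1.0
    else:
        correlation = float((p * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j))
    return contrast, correlation, energy, homogeneity


def texture_features(image, mask) -> TextureFeatureSet:
    """All eight texture descriptors of one image/mask pair."""
    mean, var, skew = gray_stats(image, mask)
    sm = mask if isinstance(mask, SegMask) else SegMask.from_array(_m(mask))
    fd = fractal_dimension(sm)
    contrast, correlation, energy, homogeneity = glcm_features(image, mask)
    return TextureFeatureSet(
        gray_mean=mean, gray_variance=var, gray_skew=skew, fractal_dim=fd,
        glcm_contrast=contrast, glcm_correlation=correlation,
        glcm_energy=energy, glcm_homogeneity=homogeneity,
        degenerate=(var == 0.0))
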