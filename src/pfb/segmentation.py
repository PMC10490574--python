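"""Proximal-femur segmentation.

Two complementary methods are provided and the better result is kept:

* **Region growing** bounded by Canny edges. A seed inside the bone is found
  either from the center of the strongest Hough circle (the femoral head is
  nearly circular) or, as a fallback, from the intensity-projection maxima.
  The region is flood-filled from the seed on the complement of the dilated
  edge map, then closed and hole-filled.
* **Active contour**: a region-based level set (morphological Chan-Vese)
  evolved from an initial circle, suited to the bright-bone/dark-background
  contrast of T1 hip slices.

Masks are scored against ground truth with the Dice similarity coefficient
DSC = 2|S∩T| / (|S|+|T|) and the Jaccard index IoU = |S∩T| / |S∪T|.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, measure, morphology, segmentation as sk_seg

from .errors import (
    EmptyMaskError,
    ParameterError,
    PfbError,
    SeedNotFoundError,
    SegmentationFailure,
    UndefinedMetricError,
)
from .image import PfbImage

# Canny hysteresis thresholds as gradient-magnitude quantiles.
CANNY_QUANTILES = (0.70, 0.90)
# Hough search radii (femoral-head scale) as fractions of the smaller image dimension.
HOUGH_RADIUS_FRACTIONS = (0.06, 0.20)
# Plausibility screen for unsupervised method selection.
SCREEN_AREA_FRACTIONS = (0.02, 0.40)
SCREEN_MIN_SOLIDITY = 0.55


def _as_array(image) -> np.ndarray:
    if isinstance(image, PfbImage):
        return image.pixels
    return np.asarray(image, dtype=float)


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered, closed (row, col) boundary of a binary mask.

    Points are the pixels of the morphological border (mask minus its
    4-connected erosion), ordered by following the longest iso-contour.
    """
    mask = np.asarray(mask, dtype=bool)
    border = mask & ~ndi.binary_erosion(mask, structure=ndi.generate_binary_structure(2, 1))
    border_set = set(zip(*np.nonzero(border)))
    if not border_set:
        raise EmptyMaskError("cannot trace the boundary of an empty mask")
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    ordered = []
    for r, c in contour:
        p = (int(round(r)), int(round(c)))
        if p not in border_set:  # snap sub-pixel contour points onto the border
            for dr, dc in ((0, 0), (0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)):
                q = (p[0] + dr, p[1] + dc)
                if q in border_set:
                    p = q
                    break
            else:
                continue
        if not ordered or ordered[-1] != p:
            ordered.append(p)
    if ordered[0] != ordered[-1]:
        ordered.append(ordered[0])
    return np.array(ordered)


@dataclasses.dataclass
class SegMask:
    """Binary segmentation result with its ordered closed boundary."""

    mask: np.ndarray
    boundary: np.ndarray
    method: str = "manual_file"  # region_growing | active_contour | manual_file
    seed: Optional[Tuple[int, int]] = None

    @classmethod
    def from_array(cls, mask: np.ndarray, method: str = "manual_file",
                   seed: Optional[Tuple[int, int]] = None) -> "SegMask":
        mask = np.asarray(mask, dtype=bool)
        n = measure.label(mask, connectivity=2).max()
        if n == 0:
            raise EmptyMaskError("mask has no foreground pixels")
        if n > 1:
            raise ParameterError(f"mask must have exactly one component, found {n}")
        return cls(mask=mask, boundary=trace_boundary(mask), method=method, seed=seed)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def _mask_of(m) -> np.ndarray:
    if isinstance(m, SegMask):
        return m.mask
    return np.asarray(m, dtype=bool)


def dsc(S, T) -> float:
    """Dice similarity coefficient 2|S∩T| / (|S|+|T|)."""
    s, t = _mask_of(S), _mask_of(T)
    if s.shape != t.shape:
        raise ParameterError("masks must be congruent grids")
    denom = s.sum() + t.sum()
    if denom == 0:
        raise UndefinedMetricError("DSC undefined for two empty masks")
    return 2.0 * np.logical_and(s, t).sum() / denom


def iou(S, T) -> float:
    """Jaccard index (intersection over union) |S∩T| / |S∪T|."""
    s, t = _mask_of(S), _mask_of(T)
    if s.shape != t.shape:
        raise ParameterError("masks must be congruent grids")
    union = np.logical_or(s, t).sum()
    if union == 0:
        raise UndefinedMetricError("IoU undefined for two empty masks")
    return np.logical_and(s, t).sum() / union


def median_filter5(image):
    """5x5 median filter (reflected edges) to suppress salt-and-pepper noise."""
    arr = _as_array(image)
    if arr.shape[0] < 5 or arr.shape[1] < 5:
        raise ParameterError(f"image {arr.shape} smaller than the 5x5 kernel")
    out = ndi.median_filter(arr, size=5, mode="reflect")
    if isinstance(image, PfbImage):
        return image.with_pixels(out)
    return out


def _canny_edges(arr: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Canny with hysteresis thresholds at gradient-magnitude quantiles.

    Quantiles are taken over the *active* gradient population (above 5% of
    the maximum) so that large flat backgrounds do not drag the thresholds
    down to the noise floor.
    """
    g = ndi.gaussian_gradient_magnitude(arr, sigma)
    gmax = g.max()
    if gmax <= 0:
        return np.zeros_like(arr, dtype=bool)
    active = g > 0.05 * gmax
    lo, hi = np.quantile(g[active], CANNY_QUANTILES)
    return feature.canny(arr, sigma=sigma, low_threshold=lo, high_threshold=hi)


def seed_by_hough(image, radius_range: Optional[Tuple[float, float]] = None,
                  *, accumulator_threshold: float = 0.3) -> Tuple[int, int]:
    """Seed pixel at the center of the strongest Hough circle.

    The femoral head is the dominant circular structure in a hip slice, so
    the highest-scoring circle with radius in ``radius_range`` (defaulting to
    15-45% of the smaller image dimension) centers inside the bone.
    """
    from skimage.transform import hough_circle, hough_circle_peaks

    arr = _as_array(image)
    if radius_range is None:
        m = min(arr.shape)
        radius_range = (HOUGH_RADIUS_FRACTIONS[0] * m, HOUGH_RADIUS_FRACTIONS[1] * m)
    rmin, rmax = radius_range
    if rmin <= 0 or rmin >= rmax:
        raise ParameterError(f"invalid radius range {radius_range}")
    edges = _canny_edges(arr)
    if not edges.any():
        raise SeedNotFoundError("no edges: cannot vote for circles")
    radii = np.arange(int(np.floor(rmin)), int(np.ceil(rmax)) + 1, 2)
    accum = hough_circle(edges, radii)
    accums, cx, cy, rad = hough_circle_peaks(accum, radii, total_num_peaks=1)
    if len(accums) == 0 or accums[0] < accumulator_threshold:
        raise SeedNotFoundError(
            f"no circle with accumulator support >= {accumulator_threshold} "
            f"in radius range {radius_range}")
    return int(cy[0]), int(cx[0])


def seed_by_histogram_max(image) -> Tuple[int, int]:
    """Seed at (argmax row-sum, argmax column-sum) of the intensity image.

    Ties break to the smallest index (numpy argmax convention).
    """
    arr = _as_array(image)
    if np.ptp(arr) == 0:
        raise SeedNotFoundError("constant image: projection maxima undefined")
    r = int(np.argmax(arr.sum(axis=1)))
    c = int(np.argmax(arr.sum(axis=0)))
    return r, c


def region_grow_canny(image, seed: Tuple[int, int], *, sigma: float = 2.0,
                      border_fraction_limit: float = 0.5) -> SegMask:
    """Region growing from ``seed``, bounded by (dilated) Canny edges.

    The 4-connected flood region containing the seed is taken on the
    complement of the 3x3-dilated edge map, then closed with a 5-px disk and
    hole-filled. A region touching more than half of the image border is a
    flood-out and raises :class:`SegmentationFailure`.
    """
    arr = _as_array(image)
    r, c = seed
    if not (0 <= r < arr.shape[0] and 0 <= c < arr.shape[1]):
        raise ParameterError(f"seed {seed} outside image {arr.shape}")
    edges = _canny_edges(arr, sigma=sigma)
    barrier = ndi.binary_dilation(edges, structure=np.ones((3, 3), bool))
    if barrier[r, c]:
        raise SeedNotFoundError(f"seed {seed} lies on an edge pixel")
    free = ~barrier
    labels, _ = ndi.label(free, structure=ndi.generate_binary_structure(2, 1))
    region = labels == labels[r, c]

    border = np.zeros_like(region)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_total = border.sum()
    if (region & border).sum() > border_fraction_limit * border_total:
        raise SegmentationFailure(
            "region flooded to the image border: no closed edge barrier")

    # Grow back across the dilated edge band so the region reaches the true
    # boundary (the flood stops a couple of pixels inside it).
    region = ndi.binary_dilation(region, structure=np.ones((3, 3), bool), iterations=2)
    region = ndi.binary_closing(region, structure=morphology.disk(5))
    region = ndi.binary_fill_holes(region)
    labels2, _ = ndi.label(region)
    region = labels2 == labels2[r, c]
    if not region[r, c] or region.sum() < 10:
        raise SegmentationFailure("grown region vanished after morphology")
    return SegMask.from_array(region, method="region_growing", seed=(r, c))


def active_contour_segment(image, init_circle: Tuple[Tuple[float, float], float],
                           *, iterations: int = 200, smoothing: int = 1) -> SegMask:
    """Region-based active contour (morphological Chan-Vese) from an initial circle.

    ``init_circle`` is ((row, col), radius). The level set is evolved for a
    fixed number of iterations; the component of the result overlapping the
    initial circle is kept and hole-filled. An (almost) empty result raises
    :class:`SegmentationFailure`.
    """
    arr = _as_array(image)
    (r0, c0), radius = init_circle
    if not (radius <= r0 < arr.shape[0] - radius and radius <= c0 < arr.shape[1] - radius):
        raise ParameterError("initial circle must lie fully inside the image")
    if np.ptp(arr) == 0:
        raise SegmentationFailure("no intensity contrast to attract the contour")
    rr, cc = np.ogrid[: arr.shape[0], : arr.shape[1]]
    init = ((rr - r0) ** 2 + (cc - c0) ** 2) <= radius ** 2
    scaled = arr / max(arr.max(), 1e-12)
    ls = sk_seg.morphological_chan_vese(scaled, num_iter=iterations,
                                        init_level_set=init, smoothing=smoothing)
    region = ls.astype(bool)
    # Chan-Vese may label the dark phase as foreground; pick the brighter phase.
    if region.any() and (~region).any():
        if arr[region].mean() < arr[~region].mean():
            region = ~region
    labels, n = ndi.label(region)
    if n == 0:
        raise SegmentationFailure("active contour collapsed to an empty region")
    overlap_counts = ndi.sum_labels(init.astype(int), labels, index=np.arange(1, n + 1))
    pick = int(np.argmax(overlap_counts)) + 1 if overlap_counts.max() > 0 else \
        int(np.argmax(ndi.sum_labels(np.ones_like(region, int), labels, index=np.arange(1, n + 1)))) + 1
    region = ndi.binary_fill_holes(labels == pick)
    if region.sum() < 10:
        raise SegmentationFailure("active contour collapsed to < 10 pixels")
    return SegMask.from_array(region, method="active_contour",
                              seed=(int(round(r0)), int(round(c0))))


def _plausible(mask: SegMask, shape: Tuple[int, int]) -> bool:
    """Screen used to pick a method when no ground truth exists."""
    area_frac = mask.area / (shape[0] * shape[1])
    lo, hi = SCREEN_AREA_FRACTIONS
    if not (lo <= area_frac <= hi):
        return False
    props = measure.regionprops(mask.mask.astype(int))[0]
    return props.solidity >= SCREEN_MIN_SOLIDITY


def segment_best(image, truth: Optional[SegMask] = None,
                 manual_mask_path=None, *, denoise: bool = True) -> SegMask:
    """Run both segmentation methods and keep the better result.

    With ground truth, "better" means higher DSC. Without it, a plausibility
    screen (single component, area within bounds, solidity above threshold)
    selects among the candidates, preferring region growing on ties. If both
    methods fail a manually delineated mask file may stand in.
    """
    arr = _as_array(image)
    work = median_filter5(arr) if denoise else arr
    candidates, failures = [], []

    try:
        try:
            seed = seed_by_hough(work)
        except SeedNotFoundError:
            seed = seed_by_histogram_max(work)
        candidates.append(region_grow_canny(work, seed))
    except PfbError as exc:
        failures.append(f"region_growing: {exc}")

    try:
        try:
            (r0, c0) = seed_by_hough(work)
            radius = 0.2 * min(arr.shape)
        except SeedNotFoundError:
            r0, c0 = arr.shape[0] / 2, arr.shape[1] / 2
            radius = 0.2 * min(arr.shape)
        candidates.append(active_contour_segment(work, ((r0, c0), radius)))
    except PfbError as exc:
        failures.append(f"active_contour: {exc}")

    if truth is not None and candidates:
        return max(candidates, key=lambda m: dsc(m, truth))
    if candidates:
        plausible = [m for m in candidates if _plausible(m, arr.shape)]
        if plausible:
            plausible.sort(key=lambda m: 0 if m.method == "region_growing" else 1)
            return plausible[0]
        failures.append("no candidate passed the plausibility screen")

    if manual_mask_path is not None:
        from .image import read_png

        return SegMask.from_array(read_png(manual_mask_path) > 127, method="manual_file")
    raise SegmentationFailure("all segmentation methods failed: " + "; ".join(failures))
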