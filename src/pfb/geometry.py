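"""Geometric features of the segmented proximal femur.

Twelve quantities are measured on the canonical (left-oriented, cropped)
mask: the head-circle center (x1, y1) and diameter W0, the mask centroid
(x, y), the neck length L1 and neck/mid-neck widths W1/W2, the shaft extent
L2 and proximal/distal shaft widths W3/W4, and the neck-shaft angle theta.

Operational definitions (the quantities are only sketched pictorially in the
source material, so these are this package's reconstruction, chosen to be
scale-equivariant and recoverable on phantoms):

* head circle: largest inscribed circle — center and radius from the maximum
  of the Euclidean distance transform (EDT);
* neck bottleneck: along the widest path (EDT-guided minimum-cost route) from
  the head center to the shaft centroid, the first local minimum of the EDT
  after leaving the head disk. W1 = twice the EDT there, L1 = its distance
  from the head center;
* W2: twice the EDT at the midpoint of the head-center-to-bottleneck segment;
* shaft axis: principal axis of the inferior third of the mask, oriented
  distally; L2 = extent of the whole mask along it; W3/W4 = twice the EDT at
  the proximal/distal third points of the shaft region's axis span;
* theta: angle between the neck axis (bottleneck-to-head direction) and the
  distal shaft axis, in degrees (anatomical neck-shaft convention, ~120-140
  on normal femurs).

Coordinates are (row, col), 0-based, origin top-left; x denotes columns and
y rows in the feature names.
"""

from __future__ import annotations

import dataclasses
from typing import Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.graph import route_through_array

from .errors import EmptyMaskError, ParameterError
from .segmentation import SegMask

#: Frame of background pixels kept around the bounding-box crop.
CROP_FRAME_PX = 5
#: Minimum mask size for meaningful geometry.
MIN_MASK_PIXELS = 100
#: Sentinel angle for rotationally degenerate (disk-like) masks.
DEGENERATE_THETA = 90.0

GEOMETRIC_FEATURE_NAMES = ["x1", "y1", "L1", "L2", "theta",
                           "W0", "W1", "W2", "W3", "W4", "x", "y"]


@dataclasses.dataclass
class GeometricFeatureSet:
    """The 12 geometric quantities, all lengths in pixels, theta in degrees."""

    x1: float
    y1: float
    L1: float
    L2: float
    theta: float
    W0: float
    W1: float
    W2: float
    W3: float
    W4: float
    x: float
    y: float
    degenerate: bool = False

    def values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in GEOMETRIC_FEATURE_NAMES])


def crop_and_orient(mask: SegMask, side: str = "left") -> SegMask:
    """Canonicalize a mask: mirror right femurs, crop to bbox + 5-px frame.

    The crop is clipped at the original grid borders, so a mask touching the
    border keeps a smaller frame on that side.
    """
    m = mask.mask
    if not m.any():
        raise EmptyMaskError("cannot canonicalize an empty mask")
    if side == "right":
        m = m[:, ::-1]
    elif side != "left":
        raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
    rows = np.nonzero(m.any(axis=1))[0]
    cols = np.nonzero(m.any(axis=0))[0]
    r0 = max(rows.min() - CROP_FRAME_PX, 0)
    r1 = min(rows.max() + CROP_FRAME_PX + 1, m.shape[0])
    c0 = max(cols.min() - CROP_FRAME_PX, 0)
    c1 = min(cols.max() + CROP_FRAME_PX + 1, m.shape[1])
    return SegMask.from_array(m[r0:r1, c0:c1], method=mask.method, seed=None)


def crop_like(mask: SegMask, image: np.ndarray, side: str = "left") -> np.ndarray:
    """Apply the same orientation/crop as :func:`crop_and_orient` to an image."""
    m = mask.mask
    img = np.asarray(image, dtype=float)
    if img.shape != m.shape:
        raise ParameterError("image and mask must be congruent")
    if side == "right":
        m = m[:, ::-1]
        img = img[:, ::-1]
    rows = np.nonzero(m.any(axis=1))[0]
    cols = np.nonzero(m.any(axis=0))[0]
    r0 = max(rows.min() - CROP_FRAME_PX, 0)
    r1 = min(rows.max() + CROP_FRAME_PX + 1, m.shape[0])
    c0 = max(cols.min() - CROP_FRAME_PX, 0)
    c1 = min(cols.max() + CROP_FRAME_PX + 1, m.shape[1])
    return img[r0:r1, c0:c1]


def _shaft_axis(mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal axis of the inferior third: (unit vector, region centroid, region pts)."""
    rows = np.nonzero(mask.any(axis=1))[0]
    r0, r1 = rows.min(), rows.max()
    inferior = mask.copy()
    inferior[: r0 + 2 * (r1 - r0) // 3] = False
    pts = np.argwhere(inferior).astype(float)
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    v = vt[0]
    if v[0] < 0:  # orient distally (down the image)
        v = -v
    return v, center, pts


def _edt_at(edt: np.ndarray, point) -> float:
    r = int(round(point[0]))
    c = int(round(point[1]))
    r = min(max(r, 0), edt.shape[0] - 1)
    c = min(max(c, 0), edt.shape[1] - 1)
    return float(edt[r, c])


def _neck_bottleneck(mask: np.ndarray, edt: np.ndarray, head: Tuple[int, int],
                     target: Tuple[int, int], in_shaft) -> Tuple[np.ndarray, float]:
    """Neck bottleneck along the widest path head -> shaft.

    The widest path (minimum-cost route through the inverse EDT) runs from
    the head center down the neck into the shaft. The neck section of the
    path is everything outside the head disk and not yet inside the shaft
    (``in_shaft`` is evaluated per path point by the caller from the shaft
    axis); the bottleneck is the middle of the plateau of near-minimal EDT
    values there, which keeps its location stable under rescaling.
    Returns (bottleneck point, half-width there).
    """
    cost = np.where(mask, 1.0 / (edt + 0.5), 1e9)
    path, _ = route_through_array(cost, head, target, fully_connected=True,
                                  geometric=True)
    path = np.asarray(path)
    evals = edt[path[:, 0], path[:, 1]]
    head_radius = edt[head]
    outside_head = np.hypot(path[:, 0] - head[0], path[:, 1] - head[1]) > 0.9 * head_radius

    sel = np.nonzero(outside_head & ~in_shaft(path))[0]
    if sel.size == 0:
        sel = np.nonzero(outside_head)[0]
    if sel.size == 0:
        return path[-1].astype(float), float(evals[-1])
    min_val = evals[sel].min()
    plateau = sel[evals[sel] <= 1.05 * min_val + 0.5]
    i = int(plateau[len(plateau) // 2])
    return path[i].astype(float), float(evals[i])


def extract_geometry(mask: SegMask) -> GeometricFeatureSet:
    """Measure the 12 geometric quantities on a canonical mask."""
    m = mask.mask
    area = int(m.sum())
    if area < MIN_MASK_PIXELS:
        raise ParameterError(f"mask too small for geometry ({area} px < {MIN_MASK_PIXELS})")

    edt = ndi.distance_transform_edt(m)
    head = np.unravel_index(int(np.argmax(edt)), edt.shape)
    head_radius = float(edt[head])
    W0 = 2.0 * head_radius
    centroid = ndi.center_of_mass(m)

    # Disk-like masks have no neck/shaft: centroid coincides with the head
    # center and the inscribed circle nearly fills the mask.
    equivalent_radius = np.sqrt(area / np.pi)
    if (np.hypot(centroid[0] - head[0], centroid[1] - head[1]) < 3.0
            and head_radius > 0.9 * equivalent_radius):
        rows = np.nonzero(m.any(axis=1))[0]
        return GeometricFeatureSet(
            x1=float(head[1]), y1=float(head[0]), L1=0.0,
            L2=float(rows.max() - rows.min() + 1), theta=DEGENERATE_THETA,
            W0=W0, W1=W0, W2=W0, W3=W0, W4=W0,
            x=float(centroid[1]), y=float(centroid[0]), degenerate=True)

    v, shaft_center, shaft_pts = _shaft_axis(m)
    target = tuple(int(round(c)) for c in shaft_center)
    if not m[target]:  # centroid of a curved region may fall outside
        idx = np.argmin(((shaft_pts - shaft_center) ** 2).sum(axis=1))
        target = tuple(int(c) for c in shaft_pts[idx])
    shaft_half = max(_edt_at(edt, shaft_center), 1.0)

    def in_shaft(points: np.ndarray) -> np.ndarray:
        # perpendicular distance from each (row, col) point to the shaft axis line
        rel = points.astype(float) - shaft_center
        perp = rel - np.outer(rel @ v, v)
        return np.hypot(perp[:, 0], perp[:, 1]) < 1.2 * shaft_half

    bottleneck, half_w1 = _neck_bottleneck(m, edt, head, target, in_shaft)
    W1 = 2.0 * half_w1
    L1 = float(np.hypot(bottleneck[0] - head[0], bottleneck[1] - head[1]))
    midpoint = ((head[0] + bottleneck[0]) / 2.0, (head[1] + bottleneck[1]) / 2.0)
    W2 = 2.0 * _edt_at(edt, midpoint)

    all_pts = np.argwhere(m).astype(float)
    proj_all = (all_pts - shaft_center) @ v
    L2 = float(proj_all.max() - proj_all.min())

    proj_shaft = (shaft_pts - shaft_center) @ v
    t0, t1 = proj_shaft.min(), proj_shaft.max()
    span = t1 - t0
    W3 = 2.0 * _edt_at(edt, shaft_center + (t0 + span / 3.0) * v)
    W4 = 2.0 * _edt_at(edt, shaft_center + (t0 + 2.0 * span / 3.0) * v)

    neck_vec = np.array([head[0], head[1]], float) - bottleneck
    norm = np.linalg.norm(neck_vec)
    if norm < 1e-9:
        theta = DEGENERATE_THETA
        degenerate = True
    else:
        cosang = float(neck_vec @ v) / norm
        theta = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        degenerate = False
        if theta < 90.0:  # report the obtuse-side (anatomical) angle
            theta = 180.0 - theta

    return GeometricFeatureSet(
        x1=float(head[1]), y1=float(head[0]), L1=L1, L2=L2, theta=theta,
        W0=W0, W1=W1, W2=W2, W3=W3, W4=W4,
        x=float(centroid[1]), y=float(centroid[0]), degenerate=degenerate)
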