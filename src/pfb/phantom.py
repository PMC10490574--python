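"""Synthetic femur phantoms and cohort emulation.

The generator draws a femur-like bright region — a circular head joined by an
oblique neck to a vertical shaft — on a darker background, with
class-dependent geometry (neck width, head radius, neck-shaft angle) and
class-dependent texture (bone intensity mean and variance). Acquisition
effects are emulated by a protocol-dependent global intensity gain (one gain
per entry of the seven-protocol cohort table below), salt-and-pepper noise,
and left/right side flipping. Every quantity in the ground-truth mask is
recoverable from the spec, so the segmentation and feature stages can be
scored without real scans.

``PROTOCOLS`` records the cohort's seven TR/TE/flip-angle acquisition
settings with their referred/healthy/unhealthy counts; the generator samples
protocols proportionally to the referred counts.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .errors import BalanceError, ParameterError, UndefinedMetricError
from .image import HEALTHY, UNHEALTHY, Dataset, PfbImage
from .segmentation import SegMask

#: The cohort's seven acquisition protocols: (weighting, TR ms, TE ms, flip
#: angle deg, referred, healthy, unhealthy). Gains are fixed per protocol to
#: emulate protocol-dependent global intensity scaling.
PROTOCOLS = [
    {"weighting": "T1", "TR": 415.0, "TE": 19.0, "flip_angle": 150.0,
     "referred": 44, "healthy": 33, "unhealthy": 11, "gain": 1.00},
    {"weighting": "T1", "TR": 536.0, "TE": 11.0, "flip_angle": 180.0,
     "referred": 43, "healthy": 31, "unhealthy": 12, "gain": 0.90},
    {"weighting": "T1", "TR": 4070.0, "TE": 33.0, "flip_angle": 180.0,
     "referred": 42, "healthy": 29, "unhealthy": 13, "gain": 1.15},
    {"weighting": "T1", "TR": 420.0, "TE": 22.0, "flip_angle": 180.0,
     "referred": 45, "healthy": 36, "unhealthy": 9, "gain": 0.95},
    {"weighting": "T2", "TR": 3600.0, "TE": 80.0, "flip_angle": 150.0,
     "referred": 45, "healthy": 19, "unhealthy": 26, "gain": 1.30},
    {"weighting": "T2", "TR": 7840.0, "TE": 109.0, "flip_angle": 150.0,
     "referred": 41, "healthy": 28, "unhealthy": 13, "gain": 1.25},
    {"weighting": "T1", "TR": 389.0, "TE": 13.42, "flip_angle": 110.0,
     "referred": 24, "healthy": 9, "unhealthy": 15, "gain": 0.80},
]

#: Cohort class sizes (healthy = T-score > -0.9).
N_HEALTHY = 185
N_UNHEALTHY = 99


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic femur phantom."""

    class_label: int = HEALTHY
    head_radius_px: float = 26.0
    neck_width_px: float = 22.0
    shaft_width_px: float = 20.0
    neck_shaft_angle_deg: float = 130.0
    bone_mean_intensity: float = 150.0
    bone_intensity_sd: float = 10.0
    background_mean: float = 30.0
    salt_pepper_fraction: float = 0.02
    protocol_gain: float = 1.0
    side: str = "left"
    rng_seed: int = 0
    height: int = 256
    width: int = 256
    neck_length_px: Optional[float] = None  # default 2.2 x head radius

    def __post_init__(self) -> None:
        if self.head_radius_px <= self.neck_width_px / 2:
            raise ParameterError("head radius must exceed half the neck width")
        for name in ("head_radius_px", "neck_width_px", "shaft_width_px",
                     "neck_shaft_angle_deg"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 <= self.salt_pepper_fraction <= 1:
            raise ParameterError("salt_pepper_fraction must be in [0, 1]")
        if self.protocol_gain <= 0:
            raise ParameterError("protocol_gain must be positive")
        if self.side not in ("left", "right"):
            raise ParameterError("side must be 'left' or 'right'")
        if self.neck_length_px is None:
            self.neck_length_px = 2.2 * self.head_radius_px


def _segment_distance(rr, cc, p, q):
    """Distance from each grid point to the segment p-q (row/col coords)."""
    pr, pc = p
    qr, qc = q
    vr, vc = qr - pr, qc - pc
    norm2 = vr * vr + vc * vc
    t = ((rr - pr) * vr + (cc - pc) * vc) / max(norm2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(rr - (pr + t * vr), cc - (pc + t * vc))


def phantom_mask_geometry(spec: PhantomSpec):
    """Ground-truth geometry of the canonical (left-side) phantom.

    Returns (mask, head_center, neck_base) where head_center and neck_base
    are (row, col) of the head-circle center and the neck-shaft junction.
    """
    H, W = spec.height, spec.width
    rr, cc = np.mgrid[0:H, 0:W].astype(float)

    shaft_col = 0.62 * W
    shaft_top, shaft_bot = 0.48 * H, 0.92 * H
    shaft = (np.abs(cc - shaft_col) <= spec.shaft_width_px / 2) & \
            (rr >= shaft_top) & (rr <= shaft_bot)

    # Neck leaves the shaft top at the neck-shaft angle, toward superior-medial.
    theta = np.deg2rad(spec.neck_shaft_angle_deg)
    p = (shaft_top, shaft_col)
    d = (np.cos(theta), -np.sin(theta))  # (drow, dcol); distal shaft axis is (+1, 0)
    head_center = (p[0] + spec.neck_length_px * d[0], p[1] + spec.neck_length_px * d[1])
    neck = _segment_distance(rr, cc, p, head_center) <= spec.neck_width_px / 2

    head = np.hypot(rr - head_center[0], cc - head_center[1]) <= spec.head_radius_px

    mask = ndi.binary_fill_holes(head | neck | shaft)
    return mask, head_center, p


def generate_phantom(spec: PhantomSpec) -> Tuple[PfbImage, SegMask]:
    """Render a phantom image and its exact ground-truth mask.

    Deterministic for a given spec (including seed); a right-side phantom is
    the horizontal mirror of the left-side phantom with the same seed.
    """
    rng = np.random.default_rng(spec.rng_seed)
    mask, _, _ = phantom_mask_geometry(spec)
    H, W = spec.height, spec.width

    pixels = np.full((H, W), float(spec.background_mean))
    bone = np.full(int(mask.sum()), float(spec.bone_mean_intensity))
    if spec.bone_intensity_sd > 0:
        bone = bone + spec.bone_intensity_sd * rng.standard_normal(bone.size)
    pixels[mask] = bone
    pixels *= spec.protocol_gain
    pixels = np.clip(pixels, 0.0, None)

    if spec.salt_pepper_fraction > 0:
        n_noise = int(round(spec.salt_pepper_fraction * H * W))
        flat = rng.choice(H * W, size=n_noise, replace=False)
        salt_value = pixels.max()
        values = np.where(rng.random(n_noise) < 0.5, salt_value, 0.0)
        pixels.flat[flat] = values

    if spec.side == "right":
        pixels = pixels[:, ::-1].copy()
        mask = mask[:, ::-1].copy()

    image = PfbImage(pixels=pixels, side=spec.side, label=spec.class_label,
                     subject_id=f"phantom-{spec.rng_seed}")
    return image, SegMask.from_array(mask, method="manual_file")


# Class-conditional generator defaults: the healthy condition, and the fully
# separated (separation = 1) unhealthy condition. Unhealthy femurs get a
# thinner neck, smaller head, straighter neck-shaft angle, lower marrow
# signal and higher intensity variance.
HEALTHY_PARAMS = dict(head_radius_px=26.0, neck_width_px=22.0, shaft_width_px=20.0,
                      neck_shaft_angle_deg=130.0, bone_mean_intensity=150.0,
                      bone_intensity_sd=10.0)
UNHEALTHY_PARAMS = dict(head_radius_px=23.0, neck_width_px=15.0, shaft_width_px=17.0,
                        neck_shaft_angle_deg=122.0, bone_mean_intensity=120.0,
                        bone_intensity_sd=18.0)
#: Per-subject relative jitter on geometry and absolute jitter on intensity.
GEOMETRY_JITTER_SD = 0.04
INTENSITY_JITTER_SD = 4.0
ANGLE_JITTER_SD = 2.0


def spec_for_subject(label: int, separation: float, rng: np.random.Generator,
                     *, size: int = 256, salt_pepper: float = 0.02) -> PhantomSpec:
    """Draw one subject's phantom spec under the class conditions.

    ``separation`` in [0, 1] interpolates the unhealthy condition between the
    healthy baseline (0: the two classes are identically distributed) and the
    fully separated condition (1).
    """
    params = dict(HEALTHY_PARAMS)
    if label == UNHEALTHY:
        for k in params:
            params[k] = params[k] + separation * (UNHEALTHY_PARAMS[k] - params[k])
    for k in ("head_radius_px", "neck_width_px", "shaft_width_px"):
        params[k] *= 1.0 + GEOMETRY_JITTER_SD * rng.standard_normal()
    params["neck_shaft_angle_deg"] += ANGLE_JITTER_SD * rng.standard_normal()
    params["bone_mean_intensity"] += INTENSITY_JITTER_SD * rng.standard_normal()
    params["bone_intensity_sd"] = max(params["bone_intensity_sd"], 1.0)

    protocol_idx = rng.choice(len(PROTOCOLS),
                              p=np.array([p["referred"] for p in PROTOCOLS], float)
                              / sum(p["referred"] for p in PROTOCOLS))
    return PhantomSpec(
        class_label=label,
        salt_pepper_fraction=salt_pepper,
        protocol_gain=PROTOCOLS[protocol_idx]["gain"],
        side="left" if rng.random() < 0.5 else "right",
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        height=size, width=size,
        **params,
    )


def generate_dataset(n_per_class: int, separation: float = 1.0, seed: int = 0,
                     *, size: int = 256, salt_pepper: float = 0.02) -> Dataset:
    """Balanced phantom cohort with ground-truth masks."""
    rng = np.random.default_rng(seed)
    images, masks = [], []
    for label in (HEALTHY, UNHEALTHY):
        for i in range(n_per_class):
            spec = spec_for_subject(label, separation, rng, size=size,
                                    salt_pepper=salt_pepper)
            img, mask = generate_phantom(spec)
            img = dataclasses.replace(img, subject_id=f"ph-{label}-{i:04d}")
            images.append(img)
            masks.append(mask)
    return Dataset(images=images, masks=masks)


def add_gaussian_noise(image, snr_db: float, rng_seed: int, *, clip: bool = True):
    """Additive white Gaussian noise at a target SNR.

    Noise variance is set so that 10*log10(P_signal / var) = ``snr_db`` with
    P_signal the mean squared intensity of the whole image. Output is clipped
    at zero by default; pass ``clip=False`` to keep the exact additive field
    (clipping truncates the noise distribution at very low SNR).
    """
    arr = image.pixels if isinstance(image, PfbImage) else np.asarray(image, float)
    if np.ptp(arr) == 0:
        raise UndefinedMetricError("SNR undefined for a constant image")
    power = float(np.mean(arr ** 2))
    sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(rng_seed)
    noisy = arr + sigma * rng.standard_normal(arr.shape)
    if not clip:
        # unclipped output may be negative, so it cannot live in a PfbImage
        return noisy
    noisy = np.clip(noisy, 0.0, None)
    if isinstance(image, PfbImage):
        return image.with_pixels(noisy)
    return noisy


def _random_rigid_jitter(pixels: np.ndarray, rng: np.random.Generator,
                         rotation_range_deg: float, shift_fraction: float,
                         *, order: int = 1) -> np.ndarray:
    angle = rng.uniform(-rotation_range_deg, rotation_range_deg)
    dy = rng.uniform(-shift_fraction, shift_fraction) * pixels.shape[0]
    dx = rng.uniform(-shift_fraction, shift_fraction) * pixels.shape[1]
    out = ndi.rotate(pixels, angle, reshape=False, order=order, mode="nearest")
    out = ndi.shift(out, (dy, dx), order=order, mode="nearest")
    return np.clip(out, 0.0, None)


def augment_minority(dataset: Dataset, rotation_range_deg: float = 40.0,
                     shift_fraction: float = 0.2, rng_seed: int = 0) -> Dataset:
    """Equalize class counts by jittered copies of minority-class images.

    Each synthetic copy is a uniform random rotation in
    [-rotation_range_deg, +rotation_range_deg] plus uniform random
    horizontal/vertical shifts of at most ``shift_fraction`` of the image
    dimension. Originals are untouched; ground-truth masks, when present,
    receive the same transform (nearest-neighbour).
    """
    labels = [im.label for im in dataset.images]
    counts = {lab: labels.count(lab) for lab in (HEALTHY, UNHEALTHY)}
    if counts[HEALTHY] == 0 or counts[UNHEALTHY] == 0:
        raise BalanceError("augmentation needs both classes present")
    if counts[HEALTHY] == counts[UNHEALTHY]:
        return dataset

    minority = HEALTHY if counts[HEALTHY] < counts[UNHEALTHY] else UNHEALTHY
    deficit = abs(counts[HEALTHY] - counts[UNHEALTHY])
    minority_idx = [i for i, lab in enumerate(labels) if lab == minority]

    rng = np.random.default_rng(rng_seed)
    images = list(dataset.images)
    masks = list(dataset.masks) if dataset.masks is not None else None
    sources = rng.choice(minority_idx, size=deficit, replace=True)
    for j, src in enumerate(sources):
        base = dataset.images[src]
        state = rng.bit_generator.state
        new_pixels = _random_rigid_jitter(base.pixels, rng, rotation_range_deg,
                                          shift_fraction)
        images.append(dataclasses.replace(
            base, pixels=new_pixels, subject_id=f"{base.subject_id}-aug{j}"))
        if masks is not None and dataset.masks[src] is not None:
            rng.bit_generator.state = state  # same transform for the mask
            m = _random_rigid_jitter(dataset.masks[src].mask.astype(float), rng,
                                     rotation_range_deg, shift_fraction, order=0)
            masks.append(SegMask.from_array(m > 0.5, method="manual_file"))
        elif masks is not None:
            masks.append(None)
    return Dataset(images=images, masks=masks)
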