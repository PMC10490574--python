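"""Image carriers and file I/O for the PFB pipeline.

A :class:`PfbImage` is a 2-D non-negative grayscale intensity grid plus the
per-subject metadata the pipeline needs: which side the femur is on, the MR
acquisition protocol (TR/TE/flip angle), and the DEXA-derived ground truth
(T-score and/or the binary bone-health label, 0 = healthy, 1 = unhealthy).

Healthy is defined as T-score > -0.9; a T-score at or below -0.9 (osteopenia
or osteoporosis range in this cohort's convention) is labelled unhealthy.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

#: T-score threshold: healthy iff t_score > T_SCORE_THRESHOLD.
T_SCORE_THRESHOLD = -0.9

HEALTHY, UNHEALTHY = 0, 1


def label_from_t_score(t_score: float) -> int:
    """Binary bone-health label from a DEXA T-score (healthy iff T > -0.9)."""
    return HEALTHY if t_score > T_SCORE_THRESHOLD else UNHEALTHY


@dataclasses.dataclass
class PfbImage:
    """2-D grayscale hip MRI slice (or phantom) with subject metadata."""

    pixels: np.ndarray
    side: str = "left"
    protocol: Optional[dict] = None  # keys: TR (ms), TE (ms), flip_angle (deg)
    subject_id: str = ""
    t_score: Optional[float] = None
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ParameterError("pixels must be a 2-D grid")
        h, w = self.pixels.shape
        if h < 32 or w < 32:
            raise ParameterError(f"image must be at least 32x32, got {h}x{w}")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("intensities must be finite")
        if self.pixels.min() < 0:
            raise ParameterError("intensities must be non-negative")
        if self.side not in ("left", "right"):
            raise ParameterError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.t_score is not None and self.label is not None:
            if self.label != label_from_t_score(self.t_score):
                raise ParameterError(
                    f"label {self.label} inconsistent with t_score {self.t_score} "
                    f"(healthy iff T > {T_SCORE_THRESHOLD})"
                )
        if self.label is not None and self.label not in (HEALTHY, UNHEALTHY):
            raise ParameterError("label must be 0 (healthy) or 1 (unhealthy)")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "PfbImage":
        """Copy of this image with replaced pixel data, metadata preserved."""
        return dataclasses.replace(self, pixels=np.asarray(pixels, dtype=float))


@dataclasses.dataclass
class Dataset:
    """Ordered collection of images with optional per-image truth masks.

    ``masks[i]`` (a :class:`pfb.segmentation.SegMask` or None) is the
    ground-truth bone region for ``images[i]`` when available.
    """

    images: list
    masks: Optional[list] = None

    def __post_init__(self) -> None:
        ids = [im.subject_id for im in self.images]
        if len(set(ids)) != len(ids):
            raise ParameterError("subject_ids must be unique")
        labels = {im.label for im in self.images if im.label is not None}
        if not labels <= {HEALTHY, UNHEALTHY}:
            raise ParameterError("labels must be 0 or 1")
        if self.masks is not None and len(self.masks) != len(self.images):
            raise ParameterError("masks must align with images")

    def __len__(self) -> int:
        return len(self.images)

    def labels(self) -> np.ndarray:
        return np.array([im.label for im in self.images])


def read_dicom(path) -> PfbImage:
    """Read a single-frame grayscale DICOM into a :class:`PfbImage`.

    Pixel values are rescaled by RescaleSlope/RescaleIntercept when present;
    TR, TE and flip angle are copied into ``protocol`` when the tags exist.
    Negative post-rescale values (possible with CT-style intercepts) are
    clipped to zero, since the carrier is a non-negative intensity grid.
    """
    import pydicom

    path = Path(path)
    try:
        ds = pydicom.dcmread(str(path), force=False)
        raw = ds.pixel_array
    except Exception as exc:
        raise FormatError(f"cannot read DICOM pixel data from {path}: {exc}") from exc
    if raw.ndim != 2:
        raise FormatError(f"{path}: expected a single-frame 2-D image, got shape {raw.shape}")
    pixels = raw.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = np.clip(pixels * slope + intercept, 0.0, None)

    protocol = {}
    for tag, key in (("RepetitionTime", "TR"), ("EchoTime", "TE"), ("FlipAngle", "flip_angle")):
        val = getattr(ds, tag, None)
        if val is not None:
            protocol[key] = float(val)
    return PfbImage(
        pixels=pixels,
        protocol=protocol or None,
        subject_id=str(getattr(ds, "PatientID", path.stem)),
    )


def read_png(path) -> np.ndarray:
    """Read an 8/16-bit grayscale PNG as a float array."""
    try:
        arr = iio.imread(Path(path))
    except Exception as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:  # collapse accidental RGB fixtures
        arr = arr[..., 0]
    return arr.astype(float)


def write_png(path, array: np.ndarray, *, bit_depth: int = 8) -> None:
    """Write a grayscale array to PNG, scaling booleans to 0/255."""
    arr = np.asarray(array)
    if arr.dtype == bool:
        out = (arr.astype(np.uint8)) * 255
    elif bit_depth == 16:
        out = np.clip(arr, 0, 65535).astype(np.uint16)
    else:
        out = np.clip(arr, 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), out)


MANIFEST_COLUMNS = [
    "subject_id", "image_path", "mask_path", "side", "t_score", "label",
    "TR", "TE", "flip_angle",
]


def read_manifest(path) -> pd.DataFrame:
    """Read a dataset manifest CSV; only subject_id/image_path are required."""
    df = pd.read_csv(path)
    for col in ("subject_id", "image_path"):
        if col not in df.columns:
            raise FormatError(f"manifest {path} missing required column {col!r}")
    return df


def load_dataset(manifest_path) -> Dataset:
    """Load images (and truth masks when listed) described by a manifest CSV.

    image_path may point to a DICOM (.dcm) or a grayscale PNG/TIFF; paths are
    resolved relative to the manifest's directory.
    """
    from .segmentation import SegMask

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = read_manifest(manifest_path)
    images, masks = [], []
    for _, row in df.iterrows():
        img_path = root / str(row["image_path"])
        if str(img_path).lower().endswith((".dcm", ".dicom")):
            img = read_dicom(img_path)
        else:
            img = PfbImage(pixels=read_png(img_path))
        protocol = {}
        for key in ("TR", "TE", "flip_angle"):
            if key in row and pd.notna(row[key]):
                protocol[key] = float(row[key])
        img = dataclasses.replace(
            img,
            subject_id=str(row["subject_id"]),
            side=str(row.get("side", "left")) if pd.notna(row.get("side", "left")) else "left",
            t_score=float(row["t_score"]) if "t_score" in row and pd.notna(row["t_score"]) else None,
            label=int(row["label"]) if "label" in row and pd.notna(row["label"]) else None,
            protocol=protocol or img.protocol,
        )
        images.append(img)
        mask_path = row.get("mask_path")
        if mask_path is not None and pd.notna(mask_path) and str(mask_path):
            masks.append(SegMask.from_array(read_png(root / str(mask_path)) > 127, method="manual_file"))
        else:
            masks.append(None)
    return Dataset(images=images, masks=None if all(m is None for m in masks) else masks)
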