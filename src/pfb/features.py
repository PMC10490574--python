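"""Assembly of the 68 primary features and the 204-length feature vector.

The primary block order is fixed: 12 geometric quantities, the 10 statistics
of curve C1-1, the 8 of C1-2, the 10 of C1-0, the 10 of C2-0, the 10 of
C4-0, 3 first-order texture statistics, the fractal dimension, and 4 GLCM
statistics (12+10+8+10+10+10+3+1+4 = 68). The full vector appends the
elementwise squares and cubes of the primaries, giving 204 values; index
i+68 is always (feature i)^2 and index i+136 is (feature i)^3.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .curves import STATS_BY_CURVE, CurveStats
from .errors import AssemblyError
from .geometry import GEOMETRIC_FEATURE_NAMES, GeometricFeatureSet
from .texture import GLCM_FEATURE_NAMES, TEXTURE_FEATURE_NAMES, TextureFeatureSet

#: Curve blocks in feature-table order.
CURVE_BLOCK_ORDER = ["C1-1", "C1-2", "C1-0", "C2-0", "C4-0"]


def primary_feature_names() -> List[str]:
    names = list(GEOMETRIC_FEATURE_NAMES)
    for curve in CURVE_BLOCK_ORDER:
        names += [f"{curve}.{stat}" for stat in STATS_BY_CURVE[curve]]
    names += TEXTURE_FEATURE_NAMES
    names += ["fractal_dim"]
    names += GLCM_FEATURE_NAMES
    return names


def feature_names() -> List[str]:
    """All 204 feature names: primaries, then squares, then cubes."""
    primaries = primary_feature_names()
    return primaries + [f"({n})^2" for n in primaries] + [f"({n})^3" for n in primaries]


N_PRIMARY = len(primary_feature_names())
N_FEATURES = 3 * N_PRIMARY


@dataclasses.dataclass
class FeatureVector:
    """One subject's 204 named feature values."""

    names: List[str]
    values: np.ndarray
    subject_id: str = ""
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != N_FEATURES or len(self.values) != N_FEATURES:
            raise AssemblyError(
                f"feature vector must have exactly {N_FEATURES} entries")
        if len(set(self.names)) != len(self.names):
            raise AssemblyError("feature names must be unique")


def assemble(geom: GeometricFeatureSet, curves: Dict[str, CurveStats],
             texture: TextureFeatureSet, *, subject_id: str = "",
             label: Optional[int] = None) -> FeatureVector:
    """Build the 204-length vector from the per-stage feature sets."""
    primaries: List[Tuple[str, float]] = list(zip(GEOMETRIC_FEATURE_NAMES,
                                                  geom.values()))
    for curve in CURVE_BLOCK_ORDER:
        cs = curves[curve]
        for stat in STATS_BY_CURVE[curve]:
            primaries.append((f"{curve}.{stat}", cs.stats[stat]))
    for name in TEXTURE_FEATURE_NAMES + ["fractal_dim"] + GLCM_FEATURE_NAMES:
        primaries.append((name, getattr(texture, name)))

    for name, value in primaries:
        if not np.isfinite(value):
            raise AssemblyError(f"non-finite value for feature {name!r}: {value}")
    base = np.array([v for _, v in primaries], dtype=float)
    values = np.concatenate([base, base ** 2, base ** 3])
    return FeatureVector(names=feature_names(), values=values,
                         subject_id=subject_id, label=label)


def extract_features(image, mask, side: str = "left", *, subject_id: str = "",
                     label: Optional[int] = None) -> FeatureVector:
    """Full per-subject feature extraction from an image and its bone mask."""
    from .curves import curve_stats, extract_curves
    from .geometry import crop_and_orient, crop_like, extract_geometry
    from .image import PfbImage
    from .segmentation import SegMask
    from .texture import texture_features

    if isinstance(image, PfbImage):
        side = image.side
        subject_id = subject_id or image.subject_id
        label = label if label is not None else image.label
        pixels = image.pixels
    else:
        pixels = np.asarray(image, dtype=float)

    canonical = crop_and_orient(mask, side)
    crop = crop_like(mask, pixels, side)
    geom = extract_geometry(canonical)
    curves = {name: curve_stats(c) for name, c in extract_curves(canonical).items()}
    texture = texture_features(crop, canonical)
    return assemble(geom, curves, texture, subject_id=subject_id, label=label)


def feature_table(vectors: List[FeatureVector]) -> pd.DataFrame:
    """Feature vectors as a DataFrame: subject_id, label, 204 named columns."""
    rows = []
    for fv in vectors:
        row = {"subject_id": fv.subject_id, "label": fv.label}
        row.update(dict(zip(fv.names, fv.values)))
        rows.append(row)
    return pd.DataFrame(rows)


def table_matrix(table: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """(X, y, names) from a feature table with subject_id/label columns."""
    names = [c for c in table.columns if c not in ("subject_id", "label")]
    X = table[names].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    return X, y, names


def standardize_fit_apply(train: np.ndarray, test: Optional[np.ndarray] = None):
    """Z-score features with mean/SD from the training rows only.

    Zero-SD (constant) training features map to 0 everywhere.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise AssemblyError("standardization needs a nonempty training set")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    train_z = np.where(sd > 0, (train - mean) / safe, 0.0)
    if test is None:
        return train_z, None
    test = np.asarray(test, dtype=float)
    test_z = np.where(sd > 0, (test - mean) / safe, 0.0)
    return train_z, test_z
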