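"""Boundary-distance curves and their statistics.

The canonical crop is probed with five 1-D "distance signals" that describe
the femur outline: for three equal horizontal bands of the crop (top,
middle, bottom), the distance from the left crop edge to the first bone
pixel of each row (curves C1-0, C1-1, C1-2); for the columns of the left
half, the distance from the top edge down to the first bone pixel (C2-0);
and for the columns of the right half, the distance from the bottom edge up
to the first bone pixel (C4-0). Rows/columns that never meet the bone are
dropped and each curve is linearly resampled to a fixed length of 64 so
crops of different sizes are comparable.

Each curve is summarized by simple signal statistics plus two slope
("ramp") descriptors:

* average ramp — the ordinary-least-squares slope of value against index;
* first-to-last-point ramp — (last - first) / (index span);
* ramp-removed signal — the signal minus slope*index, i.e. the linear trend
  taken out so that skewness and kurtosis are meaningful.

Conventions: population (biased) variance and central moments; kurtosis is
excess kurtosis. A zero-variance curve reports skew/kurtosis of 0 and is
flagged degenerate.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List

import numpy as np
from scipy import stats as sp_stats

from .errors import DegenerateCurveError, ParameterError
from .segmentation import SegMask

CURVE_NAMES = ["C1-0", "C1-1", "C1-2", "C2-0", "C4-0"]
RESAMPLE_LENGTH = 64
MIN_RAW_SAMPLES = 8

#: Statistics computed per curve, in feature-table order.
RAMP_STATS = ["min", "max", "average_ramp", "kurtosis_rr", "skew_rr",
              "first_to_last_ramp", "moment1_rr", "moment2_rr", "variance",
              "max_second_derivative"]
PLAIN_STATS = ["min", "max", "mean", "variance", "kurtosis", "skew",
               "moment1", "moment2"]
#: C1-2 gets the plain 8-statistic set; every other curve the 10 ramp-based ones.
STATS_BY_CURVE: Dict[str, List[str]] = {name: RAMP_STATS for name in CURVE_NAMES}
STATS_BY_CURVE["C1-2"] = PLAIN_STATS


@dataclasses.dataclass
class BoundaryCurve:
    """Named 1-D distance signal with its scan region and direction."""

    name: str
    values: np.ndarray
    region: tuple  # index range within the canonical crop
    direction: str  # from_left | from_top | from_bottom

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ParameterError("curve needs at least 2 samples")


@dataclasses.dataclass
class CurveStats:
    """Statistics of one boundary curve (availability depends on the curve)."""

    name: str
    stats: Dict[str, float]
    degenerate: bool = False


def _resample(values: np.ndarray, length: int = RESAMPLE_LENGTH) -> np.ndarray:
    old = np.linspace(0.0, 1.0, len(values))
    new = np.linspace(0.0, 1.0, length)
    return np.interp(new, old, values)


def extract_curves(mask: SegMask) -> Dict[str, BoundaryCurve]:
    """The five boundary-distance curves of a canonical mask."""
    m = mask.mask
    rows = np.nonzero(m.any(axis=1))[0]
    r0, r1 = rows.min(), rows.max() + 1
    band_edges = np.linspace(r0, r1, 4).astype(int)

    curves: Dict[str, BoundaryCurve] = {}
    for i, name in enumerate(["C1-0", "C1-1", "C1-2"]):
        lo, hi = band_edges[i], band_edges[i + 1]
        vals = []
        for r in range(lo, hi):
            hits = np.nonzero(m[r])[0]
            if hits.size:
                vals.append(float(hits[0]))
        if len(vals) < MIN_RAW_SAMPLES:
            raise DegenerateCurveError(f"curve {name} has only {len(vals)} raw samples")
        curves[name] = BoundaryCurve(name=name, values=_resample(np.array(vals)),
                                     region=(lo, hi), direction="from_left")

    mid_col = m.shape[1] // 2
    vals = []
    for c in range(0, mid_col):
        hits = np.nonzero(m[:, c])[0]
        if hits.size:
            vals.append(float(hits[0]))
    if len(vals) < MIN_RAW_SAMPLES:
        raise DegenerateCurveError(f"curve C2-0 has only {len(vals)} raw samples")
    curves["C2-0"] = BoundaryCurve(name="C2-0", values=_resample(np.array(vals)),
                                   region=(0, mid_col), direction="from_top")

    vals = []
    for c in range(mid_col, m.shape[1]):
        hits = np.nonzero(m[:, c])[0]
        if hits.size:
            vals.append(float(m.shape[0] - 1 - hits[-1]))
    if len(vals) < MIN_RAW_SAMPLES:
        raise DegenerateCurveError(f"curve C4-0 has only {len(vals)} raw samples")
    curves["C4-0"] = BoundaryCurve(name="C4-0", values=_resample(np.array(vals)),
                                   region=(mid_col, m.shape[1]), direction="from_bottom")
    return curves


def _values(curve) -> np.ndarray:
    if isinstance(curve, BoundaryCurve):
        return curve.values
    v = np.asarray(curve, dtype=float)
    if len(v) < 2:
        raise ParameterError("curve needs at least 2 samples")
    return v


def average_ramp(curve) -> float:
    """OLS slope of value against sample index."""
    y = _values(curve)
    x = np.arange(len(y), dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def first_to_last_ramp(curve) -> float:
    """Endpoint slope (last - first) / (index span)."""
    y = _values(curve)
    return float((y[-1] - y[0]) / (len(y) - 1))


def ramp_removed(curve) -> np.ndarray:
    """Signal with the fitted linear trend's slope component subtracted."""
    y = _values(curve)
    slope = average_ramp(y)
    return y - slope * np.arange(len(y), dtype=float)


def curve_stats(curve: BoundaryCurve) -> CurveStats:
    """The statistics listed for this curve's name (10 ramp-based, or 8 plain)."""
    y = _values(curve)
    name = curve.name if isinstance(curve, BoundaryCurve) else "C1-0"
    wanted = STATS_BY_CURVE[name]
    var = float(np.var(y))  # population convention
    degenerate = var == 0.0
    rr = ramp_removed(y)
    rr_degenerate = float(np.var(rr)) == 0.0

    out: Dict[str, float] = {}
    for key in wanted:
        if key == "min":
            out[key] = float(y.min())
        elif key == "max":
            out[key] = float(y.max())
        elif key == "mean":
            out[key] = float(y.mean())
        elif key == "variance":
            out[key] = var
        elif key == "average_ramp":
            out[key] = average_ramp(y)
        elif key == "first_to_last_ramp":
            out[key] = first_to_last_ramp(y)
        elif key == "kurtosis":
            out[key] = 0.0 if degenerate else float(sp_stats.kurtosis(y, fisher=True, bias=True))
        elif key == "skew":
            out[key] = 0.0 if degenerate else float(sp_stats.skew(y, bias=True))
        elif key == "moment1":
            out[key] = float(np.mean(y - y.mean()))
        elif key == "moment2":
            out[key] = float(np.mean((y - y.mean()) ** 2))
        elif key == "kurtosis_rr":
            out[key] = 0.0 if rr_degenerate else float(sp_stats.kurtosis(rr, fisher=True, bias=True))
        elif key == "skew_rr":
            out[key] = 0.0 if rr_degenerate else float(sp_stats.skew(rr, bias=True))
        elif key == "moment1_rr":
            out[key] = float(np.mean(rr - rr.mean()))
        elif key == "moment2_rr":
            out[key] = float(np.mean((rr - rr.mean()) ** 2))
        elif key == "max_second_derivative":
            out[key] = float(np.diff(y, 2).max())
    return CurveStats(name=name, stats=out, degenerate=degenerate)
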