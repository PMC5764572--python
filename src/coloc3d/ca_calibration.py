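"""Chromatic-aberration calibration and mean-CA correction.

A dual-labeled standard (the same epitope imaged in both colors, e.g. a
primary antibody carrying both green and red secondaries) gives per-spot
chromatic shifts CAx = Xg - Xr, CAy = Yg - Yr, CAz = Zg - Zr.  Their field
means (CAmx, CAmy, CAmz) are subtracted from raw green-red differences of
the specimen of interest:

    Sx = Xg - Xr - CAmx,  Sy = Yg - Yr - CAmy,  Sz = Zg - Zr - CAmz.

Lateral CA typically drifts slowly across the detector (tens of nm over a
few hundred pixels); an optional per-axis linear gradient model predicts the
local CA from the spot's field position instead of using the global mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CentroidPair",
    "CAGradient",
    "CACalibration",
    "compute_ca_stats",
    "fit_ca_gradient",
    "correct_displacement",
    "select_measurement_region",
]


@dataclass(frozen=True)
class CentroidPair:
    """Green and red 3D centroids of one spot, nm, plus optional metadata."""

    Xg: float
    Yg: float
    Zg: float
    Xr: float
    Yr: float
    Zr: float
    x_px: float | None = None  # field position on the detector, pixels
    y_px: float | None = None
    cell_id: str = ""
    pair_id: str = ""
    sister_id: str = ""

    @property
    def raw_difference(self) -> tuple[float, float, float]:
        """Uncorrected (Xg-Xr, Yg-Yr, Zg-Zr), nm."""
        return (self.Xg - self.Xr, self.Yg - self.Yr, self.Zg - self.Zr)

    @property
    def green(self) -> np.ndarray:
        return np.array([self.Xg, self.Yg, self.Zg])

    @property
    def red(self) -> np.ndarray:
        return np.array([self.Xr, self.Yr, self.Zr])


@dataclass(frozen=True)
class CAGradient:
    """Linear model of one CA component against the same-axis field coordinate."""

    axis: str  # "x" or "y"
    slope: float  # nm per pixel
    intercept: float  # nm
    residual_sd: float  # nm

    def predict(self, position_px: float) -> float:
        return self.intercept + self.slope * position_px


@dataclass
class CACalibration:
    """Per-axis mean and SD of the chromatic shift, with optional gradients."""

    CAmx: float
    CAmy: float
    CAmz: float
    CAsd_x: float
    CAsd_y: float
    CAsd_z: float
    n: int
    gradients: dict[str, CAGradient] = field(default_factory=dict)

    @property
    def means(self) -> tuple[float, float, float]:
        return (self.CAmx, self.CAmy, self.CAmz)

    @property
    def sds(self) -> tuple[float, float, float]:
        return (self.CAsd_x, self.CAsd_y, self.CAsd_z)


def _check_finite(pairs: list[CentroidPair]) -> None:
    for i, p in enumerate(pairs):
        vals = (p.Xg, p.Yg, p.Zg, p.Xr, p.Yr, p.Zr)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite coordinate in record {i} (pair_id={p.pair_id!r})")


def compute_ca_stats(pairs: list[CentroidPair]) -> CACalibration:
    """Sample mean and SD (n-1 denominator) of per-axis green-red shifts."""
    if len(pairs) < 2:
        raise ValueError("at least 2 pairs required to estimate CA mean and SD")
    _check_finite(pairs)
    diffs = np.array([p.raw_difference for p in pairs])
    means = diffs.mean(axis=0)
    sds = diffs.std(axis=0, ddof=1)
    return CACalibration(
        CAmx=float(means[0]),
        CAmy=float(means[1]),
        CAmz=float(means[2]),
        CAsd_x=float(sds[0]),
        CAsd_y=float(sds[1]),
        CAsd_z=float(sds[2]),
        n=len(pairs),
    )


def fit_ca_gradient(pairs: list[CentroidPair], axis: str) -> CAGradient:
    """OLS line of the CA component along ``axis`` against that field coordinate.

    Only the lateral axes are supported: the x component of CA is regressed
    on the detector x position and likewise for y.  Axial CA shows no field
    gradient and is corrected by its mean alone.
    """
    if axis not in ("x", "y"):
        raise ValueError("gradient fits are available for axis 'x' or 'y' only")
    if len(pairs) < 3:
        raise ValueError("at least 3 pairs required for a gradient fit")
    _check_finite(pairs)
    comp_idx = 0 if axis == "x" else 1
    pos = [p.x_px if axis == "x" else p.y_px for p in pairs]
    if any(v is None for v in pos):
        raise ValueError("gradient fit requires field positions (x_px/y_px) on every pair")
    pos_arr = np.asarray(pos, dtype=float)
    comp = np.array([p.raw_difference[comp_idx] for p in pairs])
    fit = stats.linregress(pos_arr, comp)
    resid = comp - (fit.intercept + fit.slope * pos_arr)
    dof = max(len(pairs) - 2, 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof))
    return CAGradient(
        axis=axis, slope=float(fit.slope), intercept=float(fit.intercept), residual_sd=residual_sd
    )


def correct_displacement(
    pair: CentroidPair, calib: CACalibration, mode: str = "mean"
) -> tuple[float, float, float]:
    """CA-corrected green-red displacement (Sx, Sy, Sz) of one spot, nm.

    ``mode="mean"`` subtracts the calibration means; ``mode="gradient"``
    subtracts the gradient-predicted lateral CA at the spot's field position
    (z always uses the mean).
    """
    dx, dy, dz = pair.raw_difference
    if mode == "mean":
        return (dx - calib.CAmx, dy - calib.CAmy, dz - calib.CAmz)
    if mode == "gradient":
        gx = calib.gradients.get("x")
        gy = calib.gradients.get("y")
        if gx is None or gy is None:
            raise ValueError("gradient mode requires fitted x and y gradients in the calibration")
        if pair.x_px is None or pair.y_px is None:
            raise ValueError("gradient mode requires the pair's field position (x_px, y_px)")
        return (dx - gx.predict(pair.x_px), dy - gy.predict(pair.y_px), dz - calib.CAmz)
    raise ValueError(f"unknown correction mode {mode!r}")


def select_measurement_region(
    pairs: list[CentroidPair],
    x_range: tuple[float, float] = (0.0, 300.0),
    y_range: tuple[float, float] = (0.0, 200.0),
) -> list[CentroidPair]:
    """Keep only pairs inside a central detector window (default 300x200 px).

    Restricting measurements to a small central region keeps the CA spread
    small; pairs without field positions are rejected.
    """
    kept = []
    for p in pairs:
        if p.x_px is None or p.y_px is None:
            continue
        if x_range[0] <= p.x_px <= x_range[1] and y_range[0] <= p.y_px <= y_range[1]:
            kept.append(p)
    return kept
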