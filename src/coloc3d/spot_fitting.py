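"""3D Gaussian centroid fitting and integrated-intensity measurement.

The centroid of a diffraction-limited spot is obtained by least-squares
fitting of a constant-background 3D Gaussian

    B + A * exp(-(x-x0)^2/2sx^2 - (y-y0)^2/2sy^2 - (z-z0)^2/2sz^2)

over a rectangular region of interest around a seed voxel.  The model is
integrated over voxel extents (per-axis CDF differences), matching how a
pixelated detector records an image, so fitted amplitudes and widths are not
biased by the coarse 200 nm axial sampling.

Integrated spot intensity above local background uses the classic
two-box estimator: a 10x10 pixel inner region centered on the spot and a
14x14 outer region whose rim estimates the background,

    Fi = I(10x10) - [I(14x14) - I(10x10)] * 100 / 96 .

Even-sized boxes cannot be symmetric about a pixel; both boxes are anchored
so the nominal center pixel is the upper-left pixel of the central 2x2 block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtr

from .synthetic_imaging import ImageStack

__all__ = ["SpotFit", "IntensityMeasurement", "fit_spot_3d", "measure_intensity"]


@dataclass(frozen=True)
class SpotFit:
    """Result of one 3D Gaussian spot fit; coordinates in nm."""

    x: float
    y: float
    z: float
    amplitude: float
    sigma_x: float
    sigma_y: float
    sigma_z: float
    background: float
    converged: bool
    residual_norm: float


@dataclass(frozen=True)
class IntensityMeasurement:
    """Integrated fluorescence above local background, counts."""

    Fi: float
    BG: float
    inner_size: int = 10
    outer_size: int = 14


def _roi_slices(seed_point, roi_half, shape):
    ix, iy, iz = (int(v) for v in seed_point)
    hx, hy, hz = (int(v) for v in roi_half)
    nz, ny, nx = shape
    for name, lo, hi, n in (
        ("x", ix - hx, ix + hx, nx),
        ("y", iy - hy, iy + hy, ny),
        ("z", iz - hz, iz + hz, nz),
    ):
        if lo < 0 or hi >= n:
            raise ValueError(f"ROI clipped by stack edge along {name}")
    if min(2 * hx + 1, 2 * hy + 1, 2 * hz + 1) < 5:
        raise ValueError("ROI must contain at least 5x5x5 voxels")
    return (
        slice(iz - hz, iz + hz + 1),
        slice(iy - hy, iy + hy + 1),
        slice(ix - hx, ix + hx + 1),
    )


def fit_spot_3d(
    stack: ImageStack,
    seed_point: tuple[int, int, int],
    roi_half: tuple[int, int, int] = (5, 5, 3),
) -> SpotFit:
    """Fit one 3D Gaussian spot around ``seed_point`` (x, y, z voxel indices).

    Returns a :class:`SpotFit` in nm.  Solver failure or a centroid landing
    within half a voxel of the ROI border yields ``converged=False`` rather
    than an exception; an ROI extending past the stack raises ``ValueError``
    naming the offending axis.
    """
    geom = stack.geometry
    sz, sy, sx = _roi_slices(seed_point, roi_half, stack.voxels.shape)
    roi = stack.voxels[sz, sy, sx].astype(float)
    if not np.any(roi):
        return SpotFit(np.nan, np.nan, np.nan, 0.0, np.nan, np.nan, np.nan, 0.0, False, 0.0)

    steps = np.array([geom.dx, geom.dy, geom.dz])
    # voxel edges within the ROI, nm, in stack coordinates
    x_edges = (np.arange(sx.start, sx.stop + 1)) * geom.dx
    y_edges = (np.arange(sy.start, sy.stop + 1)) * geom.dy
    z_edges = (np.arange(sz.start, sz.stop + 1)) * geom.dz

    # moment-based initial guess on the background-subtracted ROI
    bg0 = float(np.median(roi))
    w = np.clip(roi - bg0, 0, None)
    if w.sum() == 0:
        w = roi
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    tot = w.sum()
    x0 = float((w.sum(axis=(0, 1)) @ xc) / tot)
    y0 = float((w.sum(axis=(0, 2)) @ yc) / tot)
    z0 = float((w.sum(axis=(1, 2)) @ zc) / tot)
    sx0 = np.sqrt(max((w.sum(axis=(0, 1)) @ (xc - x0) ** 2) / tot, (geom.dx / 2) ** 2))
    sy0 = np.sqrt(max((w.sum(axis=(0, 2)) @ (yc - y0) ** 2) / tot, (geom.dy / 2) ** 2))
    sz0 = np.sqrt(max((w.sum(axis=(1, 2)) @ (zc - z0) ** 2) / tot, (geom.dz / 2) ** 2))
    a0 = max(float(roi.max() - bg0), 1e-3)

    def model(p):
        x_, y_, z_, amp, sx_, sy_, sz_, bg = p
        fx = np.diff(ndtr((x_edges - x_) / sx_))
        fy = np.diff(ndtr((y_edges - y_) / sy_))
        fz = np.diff(ndtr((z_edges - z_) / sz_))
        # amplitude parametrized as peak voxel intensity of the continuous model
        norm = (2 * np.pi) ** 1.5 * sx_ * sy_ * sz_ / np.prod(steps)
        return bg + amp * norm * fz[:, None, None] * fy[None, :, None] * fx[None, None, :]

    p0 = np.array([x0, y0, z0, a0, sx0, sy0, sz0, bg0])
    lb = np.array(
        [x_edges[0], y_edges[0], z_edges[0], 0.0, geom.dx / 10, geom.dy / 10, geom.dz / 10, 0.0]
    )
    ub = np.array(
        [
            x_edges[-1],
            y_edges[-1],
            z_edges[-1],
            np.inf,
            (x_edges[-1] - x_edges[0]),
            (y_edges[-1] - y_edges[0]),
            (z_edges[-1] - z_edges[0]),
            np.inf,
        ]
    )
    p0 = np.clip(p0, lb, ub if np.all(np.isfinite(ub)) else None)

    try:
        res = least_squares(
            lambda p: (model(p) - roi).ravel(),
            p0,
            bounds=(lb, ub),
            xtol=1e-8,
            ftol=1e-8,
            gtol=1e-8,
            max_nfev=500 * len(p0),
        )
    except Exception:
        return SpotFit(x0, y0, z0, a0, sx0, sy0, sz0, bg0, False, np.nan)

    x_, y_, z_, amp, sx_, sy_, sz_, bg = res.x
    converged = bool(res.success)
    # centroid within 0.5 voxel of the ROI border: edge artifact
    if (
        x_ < x_edges[0] + geom.dx / 2
        or x_ > x_edges[-1] - geom.dx / 2
        or y_ < y_edges[0] + geom.dy / 2
        or y_ > y_edges[-1] - geom.dy / 2
        or z_ < z_edges[0] + geom.dz / 2
        or z_ > z_edges[-1] - geom.dz / 2
    ):
        converged = False
    resid = float(np.linalg.norm(res.fun) / max(np.linalg.norm(roi), 1e-12))
    return SpotFit(
        float(x_),
        float(y_),
        float(z_),
        float(amp),
        float(sx_),
        float(sy_),
        float(sz_),
        float(bg),
        converged,
        resid,
    )


def measure_intensity(
    stack: ImageStack, center: tuple[int, int], plane: int
) -> IntensityMeasurement:
    """Two-box integrated intensity above local background in one z-plane.

    ``center`` is the (x, y) pixel index of the spot; the 10x10 inner and
    14x14 outer boxes are anchored so ``center`` is the upper-left pixel of
    their central 2x2 block.  With inner area 100 px and outer area 196 px:

        BG = [I(14x14) - I(10x10)] * 100 / 96
        Fi = I(10x10) - BG
    """
    cx, cy = (int(v) for v in center)
    img = stack.voxels[int(plane)]
    ny, nx = img.shape
    # inner 10x10: rows cy-4..cy+5, cols cx-4..cx+5; outer 14x14 adds 2 px rim
    if cx - 6 < 0 or cx + 8 > nx or cy - 6 < 0 or cy + 8 > ny:
        raise ValueError("14x14 outer region clipped by image edge")
    i10 = float(img[cy - 4 : cy + 6, cx - 4 : cx + 6].sum())
    i14 = float(img[cy - 6 : cy + 8, cx - 6 : cx + 8].sum())
    bg = (i14 - i10) * 100.0 / 96.0
    fi = i10 - bg
    return IntensityMeasurement(Fi=fi, BG=bg)
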