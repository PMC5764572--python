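"""Separation vectors, sister-axis Delta projections, angles, and summaries.

Given CA-corrected displacements (Sx, Sy, Sz) the per-spot observables are

* ``s2d = sqrt(Sx^2 + Sy^2)`` and ``s3d = sqrt(Sx^2 + Sy^2 + Sz^2)``,
* angle alpha: rotation of the in-plane component away from the sister
  (K-K) axis, ``alpha = arctan(Sy'/Sx')`` in the K-K frame,
* angle beta: elevation of the 3D vector out of the image plane,
  ``beta = arctan(Sz / s2d)``.

Angles use the plain arctan of component ratios, range (-90, 90] degrees
with boundary cases mapped to +90.  This is deliberate: for pure noise
(true separation 0) the alpha distribution is then uniform over (-90, 90)
with SD 180/sqrt(12) ~ 52 degrees, the scale observed when separations
collapse below the noise floor; a four-quadrant atan2 would spread it over
+/-180 instead.

The Delta statistic projects each sister pair's red centroids onto the axis
defined by its green centroids and averages the two outward-signed
projections.  A common shift of one whole color (chromatic aberration)
moves the two projections by equal and opposite amounts, so Delta is
intrinsically CA-corrected without any calibration standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ca_calibration import CentroidPair
from .ml_distance import MLFit, ml_fit

__all__ = [
    "SeparationRecord",
    "SeparationSummary",
    "separation_record",
    "delta_pair",
    "summarize",
]

#: Below this raw mean separation (nm) the ML fit routinely collapses to the
#: boundary and is reported as not applicable.
DEFAULT_ML_FLOOR = 18.0


@dataclass(frozen=True)
class SeparationRecord:
    """One spot's corrected separation vector and derived observables."""

    Sx: float
    Sy: float
    Sz: float
    s2d: float
    s3d: float
    alpha: float  # degrees, in-plane rotation away from the K-K axis
    beta: float  # degrees, elevation out of the image plane
    pair_id: str = ""
    sister_id: str = ""


@dataclass
class SeparationSummary:
    """Preparation-level statistics over a set of separation records."""

    n: int
    s2d_mean: float
    s2d_sd: float
    s3d_mean: float
    s3d_sd: float
    alpha_mean: float
    alpha_sd: float
    beta_mean: float
    beta_sd: float
    z_offset: float  # mean Sz, nm
    zs3d_mean: float  # 3D separation after removing the mean axial offset
    zs3d_sd: float
    delta_mean: float | None = None
    delta_sd: float | None = None
    ml2d: MLFit | None = None
    ml3d: MLFit | None = None
    ml2d_applicable: bool = False
    ml3d_applicable: bool = False


def _ratio_angle(num: float, den: float) -> float:
    """arctan(num/den) in degrees on (-90, 90], +90 at den == 0."""
    if den == 0.0:
        return 90.0 if num != 0.0 else 0.0
    return float(np.degrees(np.arctan(num / den)))


def separation_record(
    Sx: float,
    Sy: float,
    Sz: float,
    kk_axis: tuple[float, float] = (1.0, 0.0),
    pair_id: str = "",
    sister_id: str = "",
) -> SeparationRecord:
    """Build a :class:`SeparationRecord` from a corrected displacement.

    ``kk_axis`` is the in-plane sister-axis direction; the in-plane
    components are rotated into the frame where it is the x axis before the
    angles are computed.  The magnitudes s2d/s3d are rotation-invariant.
    """
    u = np.asarray(kk_axis, dtype=float)
    norm = np.hypot(u[0], u[1])
    if norm == 0:
        raise ValueError("kk_axis must be a nonzero in-plane vector")
    u = u / norm
    sx_p = Sx * u[0] + Sy * u[1]
    sy_p = -Sx * u[1] + Sy * u[0]
    s2d = float(np.hypot(sx_p, sy_p))
    s3d = float(np.sqrt(sx_p**2 + sy_p**2 + Sz**2))
    alpha = _ratio_angle(sy_p, sx_p)
    beta = _ratio_angle(Sz, s2d)
    return SeparationRecord(
        Sx=float(Sx),
        Sy=float(Sy),
        Sz=float(Sz),
        s2d=s2d,
        s3d=s3d,
        alpha=alpha,
        beta=beta,
        pair_id=pair_id,
        sister_id=sister_id,
    )


def delta_pair(
    sister1: CentroidPair, sister2: CentroidPair, axis_channel: str = "green"
) -> tuple[float, np.ndarray]:
    """Sister-axis Delta separation of one sister pair.

    The K-K axis is the unit vector between the two sisters' centroids in
    the reference channel (green by default).  Each spot's green-to-red
    displacement is projected onto this axis with outward-positive sign
    (positive pointing away from the other sister), and Delta is the mean of
    the two projections.  Common-mode shifts of one color cancel exactly.

    Returns ``(delta_nm, kk_axis_unit_vector)``.
    """
    if axis_channel == "green":
        a1, a2 = sister1.green, sister2.green
    elif axis_channel == "red":
        a1, a2 = sister1.red, sister2.red
    else:
        raise ValueError("axis_channel must be 'green' or 'red'")
    axis = a2 - a1
    norm = float(np.linalg.norm(axis))
    if norm == 0:
        raise ValueError("coincident reference-channel sister centroids: K-K axis undefined")
    u = axis / norm
    d1 = sister1.red - sister1.green
    d2 = sister2.red - sister2.green
    # outward for sister 1 is -u (away from sister 2), for sister 2 it is +u
    proj1 = float(d1 @ -u)
    proj2 = float(d2 @ u)
    return (proj1 + proj2) / 2.0, u


def summarize(
    records: list[SeparationRecord],
    delta_values: list[float] | None = None,
    ml_floor: float = DEFAULT_ML_FLOOR,
) -> SeparationSummary:
    """Preparation-level summary of separation records.

    Computes means/SDs of all observables, the axial offset diagnostic
    (``z_offset`` = mean Sz; ``zs3d`` recomputed per record from
    ``(Sx, Sy, Sz - z_offset)``), and maximum-likelihood de-biased 2D/3D
    separations.  ML results are flagged not-applicable when the raw mean
    separation is at or below ``ml_floor`` (default 18 nm), where the
    localization noise of this method makes the fit collapse to zero; the
    fitted value is still recorded.
    """
    if len(records) < 2:
        raise ValueError("at least 2 records required for a summary")
    arr = np.array([[r.Sx, r.Sy, r.Sz, r.s2d, r.s3d, r.alpha, r.beta] for r in records])
    sx, sy, sz_, s2d, s3d, alpha, beta = arr.T
    z_offset = float(sz_.mean())
    zs3d = np.sqrt(sx**2 + sy**2 + (sz_ - z_offset) ** 2)

    summary = SeparationSummary(
        n=len(records),
        s2d_mean=float(s2d.mean()),
        s2d_sd=float(s2d.std(ddof=1)),
        s3d_mean=float(s3d.mean()),
        s3d_sd=float(s3d.std(ddof=1)),
        alpha_mean=float(alpha.mean()),
        alpha_sd=float(alpha.std(ddof=1)),
        beta_mean=float(beta.mean()),
        beta_sd=float(beta.std(ddof=1)),
        z_offset=z_offset,
        zs3d_mean=float(zs3d.mean()),
        zs3d_sd=float(zs3d.std(ddof=1)),
    )
    if delta_values is not None and len(delta_values) >= 2:
        dv = np.asarray(delta_values, dtype=float)
        summary.delta_mean = float(dv.mean())
        summary.delta_sd = float(dv.std(ddof=1))

    if len(records) >= 10:
        # degenerate samples (zero spread or zero distances) have no ML fit
        try:
            summary.ml2d = ml_fit(s2d, dims=2)
            summary.ml2d_applicable = summary.s2d_mean > ml_floor
        except ValueError:
            summary.ml2d = None
        try:
            summary.ml3d = ml_fit(s3d, dims=3)
            summary.ml3d_applicable = summary.s3d_mean > ml_floor
        except ValueError:
            summary.ml3d = None
    return summary
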