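# Methods

This note documents the models, parameter choices and numerical decisions
behind `coloc3d`, and what the synthetic fixtures do and do not establish
about real data.

## Measurement model

Each fluorescent spot is a diffraction-limited image of a point-like
epitope cluster. Its centroid is estimated by least-squares fitting of a
constant-background 3D Gaussian,
`B + A·exp(−(x−x0)²/2σx² − (y−y0)²/2σy² − (z−z0)²/2σz²)`,
over a rectangular ROI. The model is *integrated over voxel extents*
(per-axis Gaussian CDF differences) rather than sampled at voxel centers,
which matters at the coarse axial sampling (200 nm steps against a
~250 nm axial PSF σ): the integrated model leaves amplitudes and widths
unbiased and makes the renderer and the fitter exact inverses on
noiseless data.

The displacement between a green and a red centroid is corrected for
chromatic aberration by subtracting the field-mean CA measured on a
dual-labeled standard, axis by axis. Summary statistics per preparation:
raw means and SDs of `s2d`, `s3d`; angles α (in-plane rotation away from
the sister K-K axis) and β (elevation out of the image plane); the
Z-offset (mean Sz) with `zs3d` recomputed after its subtraction; the
sister-pair Delta; and maximum-likelihood de-biased ML2D/ML3D.

### Angle convention

α and β are computed as `arctan` of component ratios with range
(−90°, 90°], boundary cases mapping to +90°. This single-quadrant
convention is deliberate: when the separation vanishes, the in-plane
direction is uniform and `arctan(Sy/Sx)` is uniform on (−90°, 90°), with
SD 180/√12 ≈ 52° — the diagnostic signature of a separation at the noise
floor. A four-quadrant `atan2` would spread pure noise over ±180° and
destroy that signature.

### Delta sign convention

For a sister pair, the K-K axis is the unit vector between the two
*green* centroids (the reference channel is configurable). Each
green-to-red displacement is projected onto this axis with
outward-positive sign — positive pointing away from the other sister.
This is what makes a common-mode shift of one whole channel (chromatic
aberration) contribute equal and opposite amounts at the two sisters and
cancel in the average; the cancellation is exact and is enforced to
1e−9 nm in tests.

## Distance likelihoods

With isotropic per-axis Gaussian noise σ around a true separation μ, the
measured 2D distance is Rice-distributed and the 3D distance follows the
scaled non-central chi distribution with 3 d.f. (Maxwell at μ = 0). Both
densities are implemented directly in log space: the Rice Bessel factor
uses `log I0(x) = log i0e(x) + x`, and the chi-3 two-exponential form is
evaluated as `−(r−μ)²/2σ² + log(−expm1(−2rμ/σ²))`, accurate from the
μ → 0 limit through μ/σ ≫ 1. Tests cross-check both against independent
scipy parameterizations (`stats.rice`, `stats.ncx2` transformed).

`ml_fit` maximizes the joint likelihood over μ ∈ [0, ∞), σ ∈ (0, ∞):

* the sample is rescaled to unit mean first, which makes the estimator
  exactly scale-equivariant and conditions the optimizer;
* a 50 × 50 grid pre-scan (μ linear, σ log-spaced) guards against local
  optima, followed by L-BFGS-B refinement;
* the boundary μ = 0 is handled explicitly: its profile optimum has the
  closed-form Rayleigh/Maxwell σ̂² = ⟨r²⟩/dims and is compared against
  the interior optimum; an interior "optimum" below 0.1 % of the mean
  distance is optimizer dust on the flat approach to the boundary and is
  reported as the boundary fit. `at_boundary ⇔ μ̂ = 0` always holds.

Two deliberate modelling choices:

* **A single isotropic σ is fitted** although the axial noise of the
  instrument regime is about twice the lateral. The mis-specification is
  mild and matches how such fits are used in practice; its visible
  consequence is a residual ~2 nm overestimate at μ ≈ 60 nm (ML3D ≈ 62
  at true 60) rather than exact recovery, and a strong tendency of
  pure-noise anisotropic samples to collapse to μ̂ = 0 (the anisotropy
  reads as overdispersion, which the model absorbs by inflating σ).
  For *well-specified* isotropic noise at μ = 0, by contrast, the
  boundary is hit only about half the time — the μ² parameterization is
  weakly identified there and small positive μ̂ of order σ·n^(−1/4) is
  expected. Tests assert the collapse in the anisotropic measurement
  regime, which is the one the package is about.
* Both σ̂ and the raw distance SD are reported; summaries print the raw
  SD alongside μ̂, without asserting which one a given publication's
  "± SD" refers to.

ML results are flagged not-applicable when the raw mean separation is at
or below 18 nm (configurable): with the default noise regime the fit
collapses to the boundary there, so μ̂ carries no information.

## The field simulator

The simulator reruns the complete analysis on synthetic coordinates — no
images — exactly as the error analysis of the measurement method is
defined:

* kinetochores on a grid, x = 0…280 px and y = 0…180 px at 10 px
  spacing → 29 × 19 = 551 positions per field;
* green centroid = origin + CDsd ⊙ N(0,1)³, default CDsd = (4, 4, 8) nm
  (axial centroid noise twice lateral, reflecting the ~2× worse axial
  resolution);
* red centroid = true offset (length S along the K-K = x axis, optionally
  rotated by input angles α, β) + CA deviation + (0, 0, Z-offset) +
  CDsd ⊙ N(0,1)³, with CA deviation either CAsd ⊙ N(0,1)³
  (default CAsd = (9.1, 7.5, 17.6) nm) or a linear field gradient with
  matching mean and SD;
* the correction subtracts the field-mean CA, so only the CA *deviation*
  enters the result; the code generates the deviation directly, making
  the invariance to the CA mean exact to the last bit and the all-SDs-zero
  case an exact identity (every statistic equals its input);
* Ksd > 0 adds biological spread to the separation magnitude itself
  (Gaussian SD Ksd along the true direction; an alternative isotropic
  vector mode is available), distinct from measurement noise;
* records and summaries go through the same `separation_analysis` and
  `ml_distance` code paths as real centroid tables.

Simulated Delta is defined as the corrected x component Sx per
kinetochore — the grid model has no sister pairs — giving
Delta SD = √2·CDsd_x when CAsd = 0. This differs from the experimental
sister-pair Delta (which would also cancel *local* CA) and is the basis
of `infer_cdsd`: with CAsd forced to zero and the constraint
CDsd_z = 2·CDsd_xy, bisection on CDsd_xy recovers the centroid noise
implied by a measured Delta SD. Each bisection probe reuses the same
seed, so the objective is deterministic and monotone. Note the two
published anchors for this inversion disagree internally (a stated Delta
SD target of 7.5 nm against a simulated Delta SD of 5.7 nm for the same
CDsd); the implementation reproduces the simulated value
√2 × 4 ≈ 5.7 nm, and the inversion is exposed so either target can be
used.

Gradient CA mode uses slopes of −30 nm/280 px (x) and −21 nm/180 px (y),
zero axial slope; residual Gaussian scatter tops each axis variance up to
CAsd². With the defaults the x gradient alone accounts for nearly the
whole CAx variance, and gradient and random modes give summary statistics
within 1 nm of each other — the mean-CA correction does not care how the
CA spread is arranged across the field.

Reference statistics reproduced by the acceptance suite (each averaged
over 20 seeds, tolerance 1.5 nm / 2°): S = 0 → raw S(3D) ≈ 22 nm,
α SD ≈ 51°; S = 40 → S(3D) ≈ 47 nm; S = 60 → S(3D) ≈ 63.9 nm,
ML3D ≈ 62 nm, β SD ≈ 19°; S = 100 → ML3D ≈ 101.7 nm; S = 15 → ML3D
collapses to 0 in the majority of seeds.

## Synthetic imaging fixture

The generator renders integrated-Gaussian spots with Poisson noise only:
photon-counting detection with zero camera gain/offset and no read noise,
uniform background, a spatially invariant PSF, and no spectral
bleed-through. PSF widths default to σxy = 100 nm, σz = 250 nm
(plausible for a 1.4 NA oil objective; the optics behind the published
measurements are not fully specified, so localization-precision claims
are made against this fixture's own repeat-measurement oracle, not
against printed instrument numbers). Brightness defaults to 100,000
photons per spot — the regime quoted as necessary for ~5 nm centroid
SDs in cells. On the clean fixture (background 100 counts/voxel) the
repeat-fit SD is far better than that (≈0.45 nm lateral, 1.2 nm axial
over 200 Poisson repeats), because real-cell backgrounds, fixation
variability and PSF aberrations are absent; passing these tests shows
the fitter is unbiased and noise-limited, not that any particular
microscope achieves sub-nm precision.

Spot fitting numerical choices: ROI of ±5 px laterally and ±3 planes
axially; initial guesses from background-subtracted intensity moments;
`least_squares` with 1e−8 tolerances; a fit whose centroid lands within
half a voxel of the ROI border is flagged `converged=False` (edge
artifact) rather than trusted. The two-box intensity estimator uses
even-sized regions (10×10 inner, 14×14 outer) anchored so the nominal
center pixel is the upper-left pixel of the central 2×2 block — an
arbitrary but documented resolution of the even-box centering ambiguity.

## Known limitations

* No spot detection: seeds are inputs; merged spots are not deconvolved.
* No anisotropic or censored distance likelihoods; no Bayesian posterior.
* The simulator operates on coordinates, not rendered images, so it
  propagates the stated noise SDs rather than deriving them from optics;
  Z-offset is injected, not derived from a coverslip ray model.
* CA gradients are modelled as straight lines per lateral axis; no 2D
  spatial CA maps and no third-color in-situ CA correction.
* Sister pairing is metadata supplied by the user, never inferred from
  proximity.
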