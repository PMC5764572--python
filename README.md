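# coloc3d

Two-color 3D fluorescence co-localization distance measurement with
nanometer-scale error analysis.

## The problem

Mapping protein architecture inside structures such as the human
kinetochore requires measuring the mean separation between two
fluorescently labeled epitopes to ~10 nm accuracy — an order of magnitude
below the diffraction limit. The positions of the two labels can be
localized far more precisely than they can be resolved, by fitting a 3D
Gaussian to each diffraction-limited spot, but the *distance* between two
fitted centroids is corrupted by three effects this package models and
corrects:

1. **Chromatic aberration (CA).** The same physical point imaged in two
   colors appears displaced by tens of nm. A dual-labeled standard (one
   epitope carrying both green and red secondaries) calibrates the field
   mean and SD of `CAx = Xg − Xr`, `CAy`, `CAz`; the mean is subtracted
   from every measured displacement:
   `Sx = Xg − Xr − CAmx`, and likewise for y and z.
2. **Positive distance bias.** With per-axis localization noise σ, the raw
   mean of `S(3D) = ⟨√(Sx² + Sy² + Sz²)⟩` overestimates the true
   separation μ, severely so when μ ≲ 2σ. The measured 2D distance follows
   a Rice distribution, the 3D distance a scaled non-central chi with 3
   degrees of freedom; jointly maximizing their likelihood over (μ, σ)
   de-biases the estimate (ML2D / ML3D).
3. **Axial offsets and local correction.** A wrong coverslip thickness
   produces a z-axis CA (the Z-offset, mean Sz) that inflates 3D
   distances; subtracting it from Sz recovers the unbiased value
   (zS(3D)). Independently, the sister-pair **Delta** statistic projects
   one color's centroids onto the axis defined by the other color's sister
   centroids (the K-K axis) and averages the outward-signed projections —
   common-mode chromatic shifts cancel exactly, giving a locally
   CA-corrected 1D separation.

A Monte-Carlo simulator reproduces the whole measurement on a synthetic
detector field (551 kinetochores on a 29 × 19 pixel grid) and quantifies
how centroid-determination noise (CDsd), CA spread (CAsd), Z-offset and
kinetochore-to-kinetochore variability (Ksd) inflate measured separations
and angle SDs — telling you what your instrument's SDs do to your numbers
before you believe them.

## Worked example

Simulate the measurement of a true 60 nm separation under realistic
instrument noise (CDsd = (4, 4, 8) nm, CAsd = (9.1, 7.5, 17.6) nm), 20
independent fields of 551 kinetochores:

```python
from coloc3d import SimulationConfig, simulate_field

cfg = SimulationConfig(S=60.0, n_reps=20, seed=42)
res = simulate_field(cfg)
rm = res.rep_means()
print(f"S(3D) = {rm['s3d_mean'].mean():.1f} +/- {rm['s3d_sd'].mean():.1f} nm")
print(f"ML3D  = {rm['ml3d_mu'].mean():.1f} nm")
print(res.summary.ml3d.summary())
```

```
S(3D) = 64.1 +/- 11.2 nm
ML3D  = 61.9 nm
Maximum-likelihood 3D separation fit (n = 11020)
  mu_hat    =     61.939 nm
  sigma_hat =     11.443 nm
  raw SD    =     11.247 nm
  log-lik   = -42304.562
```

The raw 3D mean overestimates the true 60 nm by ~4 nm; the
maximum-likelihood fit removes most of the bias (the residual ~2 nm comes
from fitting a single isotropic σ to noise whose axial component is twice
the lateral one). The same objects drive the angle statistics (α SD ≈ 9°,
β SD ≈ 19° at 60 nm — so a large measured angle spread need not be
biological), nuisance sweeps (`sweep_nuisance`), and the inversion
`infer_cdsd` that recovers the centroid noise implied by a measured Delta
SD.

The measurement chain itself runs on image stacks or centroid tables:

```bash
coloc3d render --n-pairs 10 --separation 60 --out field/     # synthetic stacks
coloc3d fit --stack field/green.tif --seeds field/truth.csv --out green.csv
coloc3d calibrate --pairs standard.csv --out calib.json       # CA standard
coloc3d measure --centroids centroids.csv --calibration calib.json --out out/
coloc3d mlfit --distances distances.csv --dims 3
coloc3d simulate --s 60 --n-reps 20 --out sim/
coloc3d sweep --parameter S --values 0,20,40,60,80,100 --out sweep.csv
```

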