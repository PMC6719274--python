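# Methods

## The measurement model

The pipeline estimates acute infarct volume on noncontrast head CT from the
output of intensity inhomogeneity correction (IIC). The underlying model of
the image is

```
I(x) = T(x) · B(x) + n(x)
```

with `T` piecewise-near-constant tissue intensity, `B` a spatially smooth
multiplicative field (beam-hardening "cupping" and related shading,
|B − 1| of order a few percent), and `n` noise. An early infarct is a
*violation* of this model: a focal region where `T` itself is reduced by a
few percent. A corrector constrained to smooth fields at the right scale
partially attributes the lesion to `B`, so the restored image `I/B̂` fills
the lesion in, and the difference map `D = I − I_restored` shows it as a
focal negative region sitting on top of the (hemispherically symmetric)
baseline correction. Thresholding `D` at −1.5 HU per hemisphere and
subtracting the contralateral thresholded volume from the ipsilateral one
cancels the symmetric baseline and leaves the lesion volume.

Working assumptions: one supratentorial lesion confined to one hemisphere;
baseline artifacts approximately left–right symmetric; brain parenchyma
0–50 HU; the left–right axis identifiable from NIfTI orientation metadata.
All images are reoriented to RAS+ on read so the hemisphere split is a
fixed-axis cut at the brain-mask centroid (no symmetry-plane registration;
a tilted head would bias the split).

## Correction backends

Both backends shift intensities by +100 HU (so 0–50 HU parenchyma is
strictly positive and well conditioned) and work on the log, where the
multiplicative field is additive. Both export the correction additively in
HU as `correction_field = input − restored`, exactly decomposing the input
on the brain mask, and mean-centred over the mask so a global HU offset
never counts as correction. Off the mask the restored image equals the
input.

**`em_seg`.** Per iteration: (a) fit a small Gaussian mixture
(`n_classes = 2`) to the current bias-corrected log intensities; (b) predict
each voxel's tissue intensity as the posterior-weighted class mean; (c)
smooth the prediction residual with a masked (normalised) Gaussian of FWHM
`smooth_scale_mm` and *accumulate* it into the field estimate. Two
implementation choices matter and are deliberate:

- *Class anchoring.* The mixture is re-initialised each iteration from
  fixed percentiles of the corrected intensities and refined with a single
  EM sweep. A free-running mixture on a near-unimodal brain histogram will
  dedicate a component to a focal lesion, explaining it as tissue and
  removing it from the residual — the exact opposite of what the difference
  map needs. Anchoring keeps the classes on the dominant tissue modes, the
  role GM/WM classes play on real brain.
- *Accumulation.* The field is built up as `b ← b + S(residual)` rather
  than re-estimated as `b ← S(·)` each pass. Replacement re-applies the
  smoother to the whole field every iteration; its fixed point is a
  many-fold-smoothed, amplitude-collapsed estimate. Accumulation (what both
  FAST and N4 do) converges toward a field whose *smoothed* residual
  vanishes, recovering the full amplitude of the shading.

**`hist_sharpen`.** Per multiresolution level (smoothing FWHM starting at
`smooth_scale_mm · 2^(levels−1)` and halving down to `smooth_scale_mm`),
iterate: histogram the corrected log intensities (200 bins); sharpen the
histogram by Wiener deconvolution against a Gaussian bias model of FWHM
`sharpen_fwhm` (0.15 log units) with regulariser `wiener_noise` (0.01); map
each voxel to its conditional expectation under the sharpened distribution;
smooth and accumulate the residual as above. A single-bin histogram is a
fixed point and returns the identity correction.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `smooth_scale_mm` | 20 mm | FWHM of the field smoother. This is the scale separating "shading" from "anatomy" and is the method's central trade-off: too broad and a lesion is only diffusely absorbed, so the −1.5 HU footprint becomes a wide halo that grossly over-measures small lesions and destroys the linearity of measured vs true volume; too tight and noise enters the field. 20 mm is the bias-smoothing extent FSL FAST ships with, and on the phantom it keeps recovery near-linear (r > 0.999) while the null case stays below 1 cc. |
| `n_classes` | 2 | mixture components (two-compartment segmentation). |
| `max_iters` | 50 | iteration budget; with accumulation it acts as Landweber-style regularization — components of the residual the smoother passes at attenuation λ are recovered like 1 − (1 − λ)^n, so the budget sets an effective frequency cutoff. Hitting the budget is normal and reported as `converged=False`, not an error. |
| `tol` | 1e−3 HU | stop when the largest per-iteration change of the restored intensities falls below this; measured in HU, the units of the exported field. |
| `positivity_offset` | 100 HU | pre-log shift. |
| `sharpen_fwhm`, `wiener_noise`, `hist_bins`, `levels` | 0.15, 0.01, 200, 3 | histogram-sharpening controls; `sharpen_fwhm` is wide relative to the ~0.05 log-unit spread of brain CT, so the sharpened distribution concentrates near the tissue mode and the expectation mapping pulls every voxel toward it. |

Volumetry: threshold −1.5 HU, implemented as a closed comparison
(`D ≤ −1.5` selected) for bit-exact reproducibility; midline = brain-mask
centroid along the left–right axis rounded to the nearest half-index, with
a voxel plane on the midline assigned to neither hemisphere; infarct volume
reported signed (a forced-side run may legitimately be negative and says
so in a warning). No connected-component cleanup of the selection: isolated
noise crossings are what the contralateral subtraction is for.

Brain extraction: candidates 0 ≤ HU < 50 (the 50 HU ceiling removes skull
and bone; the 0 HU floor removes air and prevents scalp bridging), erosion
2 mm, largest 26-connected component, dilation 2 mm, re-intersection,
slice-wise hole filling (5 mm slices make 3D filling unreliable on
anisotropic grids).

## The phantom: what it emulates and what it does not

The generator emulates exactly the image features the pipeline interacts
with: air background (−1000 HU), a high-HU skull shell, an ellipsoidal
uniform brain at 34 HU (≈1500 cc at the default 70/85/60 mm semiaxes), an
additive radially quadratic cupping depression inside the brain (default
3 HU at the centroid, zero at the brain edge, left–right symmetric), and
i.i.d. Gaussian noise (default 2 HU). Lesions are spheres (or azimuthal
"territory" wedges) whose voxels — by voxel-centre inclusion, so the true
volume is an exact voxel count — are reduced by `f · 34 HU`, `f` ∈ (0, 0.5].
The default grid is 128×128×30 at 1.875×1.875×5.0 mm: the clinical 24 cm
FOV and 5 mm slices at desk-scale cost; volumes in cc are matrix-independent.

Deliberately absent: gyral/ventricular anatomy, CSF, partial-volume
blurring, reconstruction physics (the cupping is a phenomenological additive
field, not simulated beam hardening), vascular-territory geometry, and any
real-anatomy hemispheric asymmetry. Consequently the phantom's null case is
symmetric to within noise, and a near-zero null-case volume here does not
promise a zero baseline on clinical scans, where anatomic asymmetry
produces a nonzero floor. Passing recovery tests demonstrate the
*mechanism* — lesion-sized hypodensities surface in the difference map and
their thresholded volume tracks truth linearly — not clinical accuracy.

The noise realisation depends only on grid shape and seed, not on the
cupping amplitude, so a phantom and its cupping-free twin share noise
voxel-for-voxel. The twin is the oracle for correction quality: the
restored image must at least halve the mean-aligned RMS inhomogeneity
residual. Mean alignment is part of the metric's definition — the exported
field is mean-free by convention, so a constant offset is not
inhomogeneity; and noise, which no smooth-field method can remove, is
present identically in both images and cancels.

## The recovery study

`run_grid` crosses true volumes (122, 45, 17 cc; 112 cc — quoted for the
largest sphere in one place in the source study — is available by config)
with density reductions (30, 20, 10, 5 %) and both backends. Each
(volume, reduction, replicate) cell generates its own phantom with seed
`base_seed + cell_index`; both backends share the cell's phantom. Reported
per cell: measured volume and recovery ratio (measured/true, %); per
(backend, reduction): Pearson r of measured vs true across the three sizes,
computed from the standard sample formula. Cell-to-cell comparisons carry
the jitter of independent noise realisations (±2–3 cc); the systematic
trends (measured volume increasing in both size and contrast) hold at
matched seeds and, at the default seed, across the grid.

Characteristic behaviour, matching the method's nature: small lesions
over-measure (a near-constant-thickness selection halo inflates small
volumes relatively more), weak-contrast lesions under-measure (the field
dip clears −1.5 HU over less of the lesion), and measured vs true is
nearly linear at fixed contrast — the recovery study's quantitative claim
(r ≥ 0.998 at 20% reduction for both backends).

## Numerical choices and degenerate inputs

- Field smoothing uses normalised (masked) Gaussian convolution; the
  denominator is the smoothed mask, so the field is unbiased up to the
  brain boundary.
- Exact decomposition is enforced in float32 at the end: the field is
  recomputed as `input − restored` after folding its residual mean into the
  restored image.
- The EM E-step is evaluated with a per-voxel log-sum-exp shift; variances
  are floored at 1e−8 so a constant region (zero variance) degenerates to
  predicted = observed, i.e. the identity correction.
- A mask smaller than `10 · n_classes` voxels is rejected; an empty
  candidate set in brain extraction raises; an all-air image raises; a
  sub-100 cc "brain" yields a warning on the mask, not an error.
- Determinism: phantoms are seeded (`numpy` PCG64); both backends are
  deterministic given inputs; grid cells derive seeds by a fixed rule, so
  entire grid results reproduce bit-for-bit.

## Known limitations

- The midline is a coordinate plane through the mask centroid; head tilt is
  not corrected (source images are assumed reoriented).
- The −1.5 HU threshold and the 20 mm field scale are coupled: re-tuning
  one without the other shifts the size-dependent bias of the estimator.
- Recovery ratios are substrate-dependent (they differ on real anatomy);
  only their trends and the linearity of measured vs true volume transfer.
- Bilateral or midline-crossing lesions violate the contralateral-baseline
  assumption by construction and will under-measure.
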