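# infarctvol

Automated acute-infarct volumetry for noncontrast head CT (NCCT), based on
intensity inhomogeneity correction (IIC).

Early ischemic change appears on NCCT as a subtle regional hypodensity —
typically only 1–4 HU below normal parenchyma — with no usable lesion
boundary, so manual ROI volumetry and edge-based segmentation both fail.
This package treats the infarct as exactly what an IIC algorithm removes: a
slowly varying intensity deficit. Brain-extracted CT is passed through a
bias-field corrector that reports a *restored* image; the voxelwise
difference map

```
D(x) = I(x) − I_restored(x)    [HU]
```

contains both baseline inhomogeneities (skull-induced cupping) and the
infarct as focal negative values. Thresholding `D ≤ −1.5 HU` in each
hemisphere and subtracting the contralateral thresholded volume (the
baseline artifact level) from the ipsilateral one yields the infarct volume
estimate

```
V_infarct = V_ipsi(D ≤ −1.5) − V_contra(D ≤ −1.5)    [cc]
```

Two interchangeable correction backends are provided:

- **`em_seg`** — segmentation-based: a Gaussian-mixture tissue model with a
  concurrent smooth bias field, estimated by EM in shifted-log intensity
  space (FSL-FAST-style);
- **`hist_sharpen`** — segmentation-free: multiresolution histogram
  sharpening by Wiener deconvolution with a smooth residual field
  (N4-style).

A synthetic head phantom (air / skull shell / uniform 34 HU brain, smooth
cupping artifact, Gaussian noise) with spherical hypodensities of exactly
known volume and fractional density reduction makes the whole method
testable without clinical data.

## Worked example

```python
from infarctvol import (CTInfarctModel, LesionSpec, PhantomSpec,
                        default_lesion_center, insert_lesion, make_head_phantom)

spec = PhantomSpec(seed=0)                      # 128x128x30, 24 cm FOV, 5 mm slices
truth = make_head_phantom(spec)                 # cupping 3 HU, noise 2 HU
lesion = LesionSpec(shape="sphere",
                    center=default_lesion_center(spec, "right"),
                    target_volume_cc=45.0, density_reduction=0.20, side="right")
truth = insert_lesion(truth, lesion)            # 20% of 34 HU = 6.8 HU hypodensity
print("true lesion volume:", round(truth.lesion_volume_true, 2), "cc")

results = CTInfarctModel(truth.image).fit(backend="em_seg", side="auto")
print(results.summary())
```

prints

```
true lesion volume: 44.44 cc
Infarct volumetry
=====================================================
backend                                      em_seg
converged                                     False
iterations                                       50
brain volume (cc)                            1496.7
threshold (HU)                                -1.50
ipsilateral side                              right
ipsilateral volume (cc)                       75.01
contralateral volume (cc)                     12.36
infarct volume (cc)                           62.65
```

The 44.4 cc sphere (voxelized from the 45 cc target) is detected on the
correct side. The ipsilateral hemisphere collects the filled-in lesion plus
baseline cupping artifacts; the contralateral 12.4 cc is the baseline alone,
and the subtraction gives the 62.7 cc estimate (overestimation of mid-size
lesions by a thin selection halo is characteristic of the method; the
estimate is nearly linear in the true volume, which is what the recovery
study quantifies). `converged False` records that the field solver used its
full iteration budget, which doubles as its regularization — see
`docs/methods.md`.

The same pipeline is scriptable from the shell:

```sh
infarctvol phantom --out ph/ --seed 0
infarctvol volume --in ph/phantom.nii.gz --backend em_seg --side auto --report report.json
infarctvol simulate --out results/   # full recovery grid
```

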