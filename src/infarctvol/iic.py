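"""Intensity inhomogeneity correction (IIC) for brain-masked head CT.

Two backends estimate a slowly varying intensity field on the brain mask and
report a "restored" image with that field removed:

``em_seg``
    Segmentation-based correction in the style of EM tissue classification
    with a concurrent bias field.  Masked intensities are shifted to
    positivity and log-transformed; each iteration fits a small Gaussian
    mixture to the bias-corrected intensities, predicts every voxel's
    expected tissue intensity from the posterior class memberships, and
    smooths the prediction residual into the field estimate.

``hist_sharpen``
    Histogram-sharpening correction in the style of N4: the histogram of
    corrected log intensities is deconvolved (Wiener) against a Gaussian
    blur model of the bias, each voxel is mapped to its expected sharpened
    intensity, and the residual is accumulated into a smooth field over a
    multiresolution schedule.

Both export the correction additively in HU: ``correction_field = input -
restored`` on the mask, mean-centred so a global HU shift never counts as
correction.  The decomposition ``input = restored + correction_field`` is
exact on the mask, and the restored image equals the input off-mask.

The whole volumetry method rests on the field picking lesions up: the
correction "fills in" a focal hypodensity, so input minus restored is
negative there, and that dip is what gets thresholded downstream.  The
default smoothing scale (20 mm FWHM, the bias-smoothing extent FSL FAST
ships with) is broad against noise and voxel structure but tight enough to
follow infarct-sized hypodensities, which keeps the thresholded footprint
close to the lesion across lesion sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .brainextract import BrainMask
from .io_nifti import CTVolume

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

BACKENDS = ("em_seg", "hist_sharpen")


@dataclass
class IICParams:
    """Tuning parameters shared by both correction backends.

    ``smooth_scale_mm`` is the FWHM of the Gaussian field smoother; it must
    be large against the voxel spacing.  ``tol`` is the convergence
    threshold on the maximum per-iteration field update, in HU (the units
    of the exported correction field).  ``positivity_offset`` shifts HU
    into a strictly positive range before the log transform; 100 HU
    conditions the log well on 0-50 HU parenchyma.
    """

    backend: str = "em_seg"
    n_classes: int = 2
    smooth_scale_mm: float = 20.0
    max_iters: int = 50
    tol: float = 1e-3
    hist_bins: int = 200
    wiener_noise: float = 0.01
    sharpen_fwhm: float = 0.15  # FWHM of the assumed bias blur, log units
    levels: int = 3
    positivity_offset: float = 100.0
    em_substeps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"backend must be one of {BACKENDS}, got {self.backend!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iters < 1 or self.levels < 1:
            raise ValueError("max_iters and levels must be >= 1")


@dataclass
class IICResult:
    """Output of a correction backend.

    ``restored`` is the corrected image (equal to the input off-mask);
    ``correction_field`` is ``input - restored`` in HU, zero off-mask and
    mean-free on the mask.
    """

    restored: CTVolume
    correction_field: np.ndarray
    iterations: int
    converged: bool
    backend: str


def _check_inputs(vol: CTVolume, mask: BrainMask, params: IICParams) -> np.ndarray:
    m = mask.mask
    if m.shape != vol.data.shape:
        raise ValueError(f"mask shape {m.shape} does not match volume {vol.data.shape}")
    if not m.any():
        raise ValueError("empty brain mask")
    if m.sum() < 10 * params.n_classes:
        raise ValueError(
            f"mask has {int(m.sum())} voxels; too small for {params.n_classes} classes"
        )
    lo = float(vol.data[m].min())
    if lo + params.positivity_offset <= 1.0:
        raise ValueError(
            f"positivity_offset {params.positivity_offset} too small for "
            f"minimum masked HU {lo:.1f}"
        )
    return m


class _MaskedSmoother:
    """Normalised Gaussian convolution restricted to a mask.

    Smoothing a field only where it is defined requires dividing the blurred
    masked field by the blurred mask, otherwise the zeros outside bleed in.
    """

    def __init__(self, mask: np.ndarray, spacing, fwhm_mm: float):
        self.mask = mask
        self.sigma_vox = [fwhm_mm * _FWHM_TO_SIGMA / s for s in spacing]
        self._denom = ndimage.gaussian_filter(mask.astype(np.float64), self.sigma_vox)
        self._denom[self._denom < 1e-12] = 1.0

    def __call__(self, values: np.ndarray) -> np.ndarray:
        """Smooth ``values`` (defined on the mask) and mean-centre on-mask."""
        num = ndimage.gaussian_filter(np.where(self.mask, values, 0.0), self.sigma_vox)
        out = num / self._denom
        out[~self.mask] = 0.0
        out[self.mask] -= out[self.mask].mean()
        return out


def _finalize(vol, m, y, b, iterations, converged, backend, offset) -> IICResult:
    restored_data = vol.data.astype(np.float64).copy()
    restored_data[m] = np.exp(y - b[m]) - offset
    field = np.zeros_like(restored_data)
    field[m] = vol.data[m].astype(np.float64) - restored_data[m]
    # exact zero-mean in HU: fold the residual mean back into the restored image
    field[m] -= field[m].mean()
    restored_data[m] = vol.data[m] - field[m]
    restored = CTVolume(
        restored_data.astype(np.float32), vol.spacing, vol.axis_codes, vol.origin
    )
    # recompute in float32 so input = restored + field holds to float precision
    field32 = np.zeros(vol.data.shape, dtype=np.float32)
    field32[m] = vol.data[m] - restored.data[m]
    return IICResult(restored, field32, iterations, converged, backend)


def _em_predict(c: np.ndarray, params: IICParams) -> np.ndarray:
    """Per-voxel expected tissue intensity under an anchored mixture.

    Class means are re-initialised from evenly spaced percentiles of the
    current corrected intensities and refined with ``em_substeps`` EM
    sweeps.  Anchoring to the bulk percentiles keeps the classes on the
    dominant tissue modes: a free-running mixture would dedicate a class to
    a focal lesion and thereby remove it from the residual, which is the
    opposite of what the difference map needs.
    """
    k = params.n_classes
    qs = 100.0 * (np.arange(k) + 0.5) / k
    means = np.percentile(c, qs)
    var0 = max(float(c.var()), 1e-8)
    variances = np.full(k, var0)
    weights = np.full(k, 1.0 / k)

    resp = None
    for _ in range(max(1, params.em_substeps)):
        # E-step
        log_p = (
            np.log(weights)[None, :]
            - 0.5 * np.log(2 * np.pi * variances)[None, :]
            - 0.5 * (c[:, None] - means[None, :]) ** 2 / variances[None, :]
        )
        log_p -= log_p.max(axis=1, keepdims=True)
        resp = np.exp(log_p)
        resp /= resp.sum(axis=1, keepdims=True)
        # M-step
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / nk.sum()
        means = (resp * c[:, None]).sum(axis=0) / nk
        variances = (resp * (c[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, 1e-8)

    return resp @ means


def correct_em_seg(vol: CTVolume, mask: BrainMask, params: IICParams | None = None) -> IICResult:
    """Segmentation-based (EM mixture + smooth field) correction."""
    params = params or IICParams(backend="em_seg")
    m = _check_inputs(vol, mask, params)
    y = np.log(vol.data[m].astype(np.float64) + params.positivity_offset)
    smoother = _MaskedSmoother(m, vol.spacing, params.smooth_scale_mm)

    b = np.zeros(vol.data.shape, dtype=np.float64)
    converged = False
    it = 0
    prev = np.exp(y)
    for it in range(1, params.max_iters + 1):
        c = y - b[m]
        predicted = _em_predict(c, params)
        residual = np.zeros_like(b)
        residual[m] = c - predicted
        # accumulate: re-smoothing the whole field every pass would compound
        # the smoother's attenuation and collapse the estimate
        db = smoother(residual)
        b = b + db
        b[~m] = 0.0
        b[m] -= b[m].mean()
        cur = np.exp(y - b[m])
        delta_hu = float(np.abs(cur - prev).max())
        prev = cur
        if delta_hu < params.tol:
            converged = True
            break
    return _finalize(vol, m, y, b, it, converged, "em_seg", params.positivity_offset)


def _sharpen_expectation(c: np.ndarray, params: IICParams):
    """Map each corrected log intensity to its expected sharpened value.

    The histogram of ``c`` is modelled as the true intensity distribution
    blurred by a Gaussian of FWHM ``sharpen_fwhm``; Wiener deconvolution
    recovers the sharpened distribution, and the conditional expectation
    E[true | observed] is evaluated on the bin grid and interpolated.

    Returns the per-voxel expectation, or None for a degenerate
    (single-bin) histogram.
    """
    lo, hi = float(c.min()), float(c.max())
    if hi - lo < 1e-12:
        return None
    nbins = params.hist_bins
    hist, edges = np.histogram(c, bins=nbins, range=(lo, hi))
    if np.count_nonzero(hist) < 2:
        return None
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    sigma_bins = params.sharpen_fwhm * _FWHM_TO_SIGMA / width
    n_pad = int(2 ** np.ceil(np.log2(2 * nbins)))
    f = np.zeros(n_pad)
    f[:nbins] = hist / hist.sum()

    freq = np.fft.fftfreq(n_pad)
    # unit-mass Gaussian kernel in the Fourier domain (real, centred)
    H = np.exp(-2.0 * (np.pi * freq * sigma_bins) ** 2)
    F = np.fft.fft(f)
    f_sharp = np.real(np.fft.ifft(F * H / (H * H + params.wiener_noise)))
    f_sharp = np.maximum(f_sharp[:nbins], 0.0)
    if f_sharp.sum() <= 0:
        return None
    f_sharp /= f_sharp.sum()

    # conditional expectation under the blur model, via two convolutions
    pad = np.zeros(n_pad)
    pad[:nbins] = f_sharp
    num_k = np.real(np.fft.ifft(np.fft.fft(pad * np.pad(centers, (0, n_pad - nbins))) * H))
    den_k = np.real(np.fft.ifft(np.fft.fft(pad) * H))
    num = num_k[:nbins]
    den = den_k[:nbins]
    expected = np.where(den > 1e-12, num / np.maximum(den, 1e-12), centers)
    return np.interp(c, centers, expected)


def correct_hist_sharpen(
    vol: CTVolume, mask: BrainMask, params: IICParams | None = None
) -> IICResult:
    """Histogram-sharpening (Wiener deconvolution, N4-style) correction.

    The smoothing scale starts at ``smooth_scale_mm * 2**(levels-1)`` and
    halves per level down to ``smooth_scale_mm``, coarse to fine.
    """
    params = params or IICParams(backend="hist_sharpen")
    m = _check_inputs(vol, mask, params)
    y = np.log(vol.data[m].astype(np.float64) + params.positivity_offset)

    b = np.zeros(vol.data.shape, dtype=np.float64)
    total_it = 0
    converged = False
    prev = np.exp(y)
    for level in range(params.levels):
        fwhm = params.smooth_scale_mm * 2.0 ** (params.levels - 1 - level)
        smoother = _MaskedSmoother(m, vol.spacing, fwhm)
        level_converged = False
        for _ in range(params.max_iters):
            total_it += 1
            c = y - b[m]
            expected = _sharpen_expectation(c, params)
            if expected is None:  # degenerate histogram: nothing to correct
                level_converged = True
                break
            residual = np.zeros_like(b)
            residual[m] = c - expected
            db = smoother(residual)
            b = b + db
            b[~m] = 0.0
            b[m] -= b[m].mean()
            cur = np.exp(y - b[m])
            delta_hu = float(np.abs(cur - prev).max())
            prev = cur
            if delta_hu < params.tol:
                level_converged = True
                break
        converged = level_converged
    return _finalize(vol, m, y, b, total_it, converged, "hist_sharpen", params.positivity_offset)


def correct(vol: CTVolume, mask: BrainMask, params: IICParams | None = None) -> IICResult:
    """Dispatch to the backend named in ``params.backend``."""
    params = params or IICParams()
    if params.backend == "em_seg":
        return correct_em_seg(vol, mask, params)
    return correct_hist_sharpen(vol, mask, params)
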