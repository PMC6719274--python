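"""Model/Results interface for the whole volumetry pipeline.

`CTInfarctModel` holds a head CT and the pipeline configuration;
:meth:`CTInfarctModel.fit` runs brain extraction, intensity inhomogeneity
correction and hemispheric threshold volumetry and returns an
:class:`InfarctVolumetryResults` carrying the estimates, diagnostics and a
``summary()`` table, with plotting and NIfTI export attached.
"""

from __future__ import annotations

import numpy as np

from . import brainextract, io_nifti, volumetry
from .brainextract import BrainMask
from .iic import IICParams, IICResult, correct
from .io_nifti import CTVolume
from .volumetry import DifferenceMap, VolumeReport


class CTInfarctModel:
    """Acute infarct volumetry model for a noncontrast head CT.

    Parameters
    ----------
    volume : CTVolume
        The head CT in Hounsfield units.
    hu_low, hu_high : float
        Brain-extraction HU window (default 0-50; the 50 HU ceiling removes
        skull and bone).
    erosion_mm, dilation_mm : float
        Morphology radii of the brain extraction.
    iic_params : IICParams, optional
        Correction settings; the backend given here is overridden by the
        ``backend`` argument of :meth:`fit`.
    """

    def __init__(
        self,
        volume: CTVolume,
        *,
        hu_low: float = 0.0,
        hu_high: float = 50.0,
        erosion_mm: float = 2.0,
        dilation_mm: float = 2.0,
        iic_params: IICParams | None = None,
    ):
        self.volume = volume
        self.hu_low = hu_low
        self.hu_high = hu_high
        self.erosion_mm = erosion_mm
        self.dilation_mm = dilation_mm
        self.iic_params = iic_params or IICParams()
        self._brain_mask: BrainMask | None = None

    @classmethod
    def from_file(cls, path, **kwargs) -> "CTInfarctModel":
        """Build a model from a NIfTI-1 file."""
        return cls(io_nifti.read_volume(path), **kwargs)

    @property
    def brain_mask(self) -> BrainMask:
        """Extracted brain mask (computed once, cached)."""
        if self._brain_mask is None:
            self._brain_mask = brainextract.extract_brain(
                self.volume,
                hu_low=self.hu_low,
                hu_high=self.hu_high,
                erosion_mm=self.erosion_mm,
                dilation_mm=self.dilation_mm,
            )
        return self._brain_mask

    def fit(
        self,
        backend: str = "em_seg",
        side: str = "auto",
        threshold_hu: float = volumetry.DEFAULT_THRESHOLD_HU,
    ) -> "InfarctVolumetryResults":
        """Run the pipeline and return the fitted results.

        Parameters
        ----------
        backend : {"em_seg", "hist_sharpen"}
            Inhomogeneity-correction backend.
        side : {"auto", "left", "right"}
            Ipsilateral (infarct) side; "auto" picks the hemisphere with the
            larger thresholded correction volume.
        threshold_hu : float
            Upper HU threshold on the difference map (default -1.5).
        """
        import dataclasses

        params = dataclasses.replace(self.iic_params, backend=backend)
        mask = self.brain_mask
        iic_result = correct(self.volume, mask, params)
        report = volumetry.estimate_infarct_volume(
            self.volume, mask, iic_result, side_ipsi=side, upper_hu=threshold_hu
        )
        dmap = volumetry.difference_map(self.volume, iic_result, mask)
        return InfarctVolumetryResults(self, mask, iic_result, dmap, report)


class InfarctVolumetryResults:
    """Results of a fitted :class:`CTInfarctModel`."""

    def __init__(
        self,
        model: CTInfarctModel,
        brain_mask: BrainMask,
        iic_result: IICResult,
        diff_map: DifferenceMap,
        report: VolumeReport,
    ):
        self.model = model
        self.brain_mask = brain_mask
        self.iic_result = iic_result
        self.diff_map = diff_map
        self.report = report

    @property
    def infarct_cc(self) -> float:
        return self.report.infarct_cc

    @property
    def restored(self) -> CTVolume:
        return self.iic_result.restored

    @property
    def selection(self) -> np.ndarray:
        """Thresholded difference-map voxels (the counted selection)."""
        return volumetry.threshold_map(self.diff_map, self.report.threshold_hu)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        r = self.report
        rows = [
            ("backend", r.backend),
            ("converged", str(self.iic_result.converged)),
            ("iterations", str(self.iic_result.iterations)),
            ("brain volume (cc)", f"{self.brain_mask.volume_cc:.1f}"),
            ("threshold (HU)", f"{r.threshold_hu:.2f}"),
            ("ipsilateral side", r.side_ipsi),
            ("ipsilateral volume (cc)", f"{r.vol_ipsi_cc:.2f}"),
            ("contralateral volume (cc)", f"{r.vol_contra_cc:.2f}"),
            ("infarct volume (cc)", f"{r.infarct_cc:.2f}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Infarct volumetry", "=" * (width + 28)]
        lines += [f"{k:<{width}}  {v:>24}" for k, v in rows]
        for w in self.brain_mask.warnings + r.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def save(self, out_dir, prefix: str = "volumetry") -> dict:
        """Write restored image, difference map, selection mask and report."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "restored": out / f"{prefix}_restored.nii.gz",
            "difference_map": out / f"{prefix}_diffmap.nii.gz",
            "selection": out / f"{prefix}_selection.nii.gz",
            "report": out / f"{prefix}_report.json",
        }
        io_nifti.write_volume(self.restored, paths["restored"])
        dmap_vol = CTVolume(
            self.diff_map.values.astype(np.float32),
            self.model.volume.spacing,
            self.model.volume.axis_codes,
            self.model.volume.origin,
        )
        io_nifti.write_volume(dmap_vol, paths["difference_map"])
        io_nifti.write_mask(self.selection, self.model.volume, paths["selection"])
        paths["report"].write_text(json.dumps(self.report.to_dict(), indent=2))
        return {k: str(v) for k, v in paths.items()}

    def plot_difference_map(self, slice_index: int | None = None, ax=None):
        """Show one axial slice of the difference map with the selection."""
        import matplotlib.pyplot as plt

        if slice_index is None:
            occupied = np.nonzero(self.brain_mask.mask.any(axis=(0, 1)))[0]
            slice_index = int(occupied[len(occupied) // 2])
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(
            self.diff_map.values[:, :, slice_index].T,
            cmap="coolwarm",
            vmin=-5,
            vmax=5,
            origin="lower",
        )
        sel = self.selection[:, :, slice_index].T
        ax.contour(sel.astype(float), levels=[0.5], colors="k", linewidths=0.8)
        ax.set_title(f"difference map (HU), slice {slice_index}")
        ax.figure.colorbar(im, ax=ax, label="HU correction")
        return ax
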