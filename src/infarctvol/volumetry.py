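"""Infarct volumetry from a difference map.

The difference map (input minus restored image, in HU) is split into
ipsilateral and contralateral hemispheres at the brain-mask centroid along
the left-right axis, thresholded at an upper value of -1.5 HU (a voxel is
selected iff its correction is -1.5 HU or more negative), and the
contralateral thresholded volume — the baseline inhomogeneity — is
subtracted from the ipsilateral one to yield the infarct volume in cc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .brainextract import BrainMask
from .iic import IICResult
from .io_nifti import CTVolume

DEFAULT_THRESHOLD_HU = -1.5


@dataclass
class DifferenceMap:
    """Voxelwise HU correction (input - restored) on the brain mask."""

    values: np.ndarray
    mask: BrainMask

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.mask.shape:
            raise ValueError("difference map and mask shapes differ")


@dataclass
class HemisphereSplit:
    ipsi_mask: np.ndarray
    contra_mask: np.ndarray
    midline_index: float
    side_ipsi: str


@dataclass
class VolumeReport:
    """Thresholded difference-map volumes per hemisphere and their difference.

    ``infarct_cc`` is signed: a forced-side run on a lesion-free or
    wrong-side image legitimately reports a negative volume (with a
    warning), which is diagnostic and must not be clamped.
    """

    vol_ipsi_cc: float
    vol_contra_cc: float
    infarct_cc: float
    threshold_hu: float
    side_ipsi: str
    backend: str
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "vol_ipsi_cc": self.vol_ipsi_cc,
            "vol_contra_cc": self.vol_contra_cc,
            "infarct_cc": self.infarct_cc,
            "threshold_hu": self.threshold_hu,
            "side_ipsi": self.side_ipsi,
            "backend": self.backend,
            "warnings": list(self.warnings),
        }


def difference_map(input_vol: CTVolume, result: IICResult, mask: BrainMask) -> DifferenceMap:
    """Input minus restored, in HU, zero off-mask."""
    if input_vol.data.shape != result.restored.data.shape:
        raise ValueError("input and restored grids differ in shape")
    if input_vol.data.shape != mask.mask.shape:
        raise ValueError("input and mask grids differ in shape")
    values = np.where(
        mask.mask, input_vol.data.astype(np.float64) - result.restored.data, 0.0
    )
    return DifferenceMap(values, mask)


def _lr_halves(mask: BrainMask, vol: CTVolume):
    """Left/right half-masks about the brain centroid along the LR axis.

    The midline is the mask centroid rounded to the nearest half-index; when
    it lands on a voxel plane, that plane belongs to neither hemisphere,
    keeping the partition unbiased.
    """
    ax = vol.lr_axis
    m = mask.mask
    idx = np.nonzero(m)[ax]
    if idx.size == 0:
        raise ValueError("empty brain mask")
    centroid = float(idx.mean())
    c = round(2.0 * centroid) / 2.0  # nearest half-index
    coords = np.arange(m.shape[ax]).reshape(
        [-1 if k == ax else 1 for k in range(3)]
    )
    low = m & (coords < c)
    high = m & (coords > c)
    # axis code tells which end of the axis is patient-right
    right_is_high = vol.axis_codes[ax] == "R"
    left = low if right_is_high else high
    right = high if right_is_high else low
    return left, right, c


def split_hemispheres(mask: BrainMask, vol: CTVolume, side_ipsi: str) -> HemisphereSplit:
    """Partition the brain mask into ipsilateral and contralateral halves.

    ``side_ipsi`` must be ``"left"`` or ``"right"``; automatic side
    selection is performed by :func:`estimate_infarct_volume`.
    """
    if side_ipsi not in ("left", "right"):
        raise ValueError(
            f"side_ipsi must be 'left' or 'right' here (got {side_ipsi!r}); "
            "'auto' is resolved by estimate_infarct_volume"
        )
    left, right, c = _lr_halves(mask, vol)
    if not left.any() or not right.any():
        raise ValueError("hemisphere split produced an empty hemisphere")
    ipsi, contra = (left, right) if side_ipsi == "left" else (right, left)
    return HemisphereSplit(ipsi, contra, c, side_ipsi)


def threshold_map(dmap: DifferenceMap, upper_hu: float = DEFAULT_THRESHOLD_HU) -> np.ndarray:
    """Select on-mask voxels with correction at or below ``upper_hu``.

    The threshold is closed: a voxel at exactly ``upper_hu`` is selected.
    """
    if upper_hu >= 0:
        raise ValueError(f"upper threshold must be negative, got {upper_hu}")
    return dmap.mask.mask & (dmap.values <= upper_hu)


def masked_volume_cc(selection: np.ndarray, spacing) -> float:
    """Volume in cc of a binary selection on a grid with ``spacing`` mm."""
    dx, dy, dz = spacing
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    return float(np.count_nonzero(selection)) * dx * dy * dz / 1000.0


def estimate_infarct_volume(
    input_vol: CTVolume,
    mask: BrainMask,
    result: IICResult,
    side_ipsi: str = "auto",
    upper_hu: float = DEFAULT_THRESHOLD_HU,
) -> VolumeReport:
    """Full volumetry: difference map, threshold, hemispheric subtraction.

    With ``side_ipsi="auto"`` the ipsilateral side is the hemisphere with
    the larger thresholded volume (ties resolve to the right).
    """
    dmap = difference_map(input_vol, result, mask)
    selection = threshold_map(dmap, upper_hu)
    left, right, _ = _lr_halves(mask, input_vol)
    if not left.any() or not right.any():
        raise ValueError("hemisphere split produced an empty hemisphere")
    vol_left = masked_volume_cc(selection & left, input_vol.spacing)
    vol_right = masked_volume_cc(selection & right, input_vol.spacing)

    warnings: list[str] = []
    if side_ipsi == "auto":
        side_ipsi = "right" if vol_right >= vol_left else "left"
    elif side_ipsi not in ("left", "right"):
        raise ValueError(f"side_ipsi must be left, right or auto, got {side_ipsi!r}")

    vol_ipsi, vol_contra = (
        (vol_left, vol_right) if side_ipsi == "left" else (vol_right, vol_left)
    )
    infarct = vol_ipsi - vol_contra
    if infarct < 0:
        warnings.append(
            f"negative infarct volume {infarct:.2f} cc on forced side {side_ipsi}"
        )
    return VolumeReport(
        vol_ipsi_cc=vol_ipsi,
        vol_contra_cc=vol_contra,
        infarct_cc=infarct,
        threshold_hu=upper_hu,
        side_ipsi=side_ipsi,
        backend=result.backend,
        warnings=warnings,
    )
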