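"""Brain extraction for head CT by HU thresholding and morphology.

Skull and bone are removed by keeping voxels in a parenchymal HU window
(default 0-50 HU), the largest connected soft-tissue component is isolated
with an erode / select / dilate sequence, and holes are filled per axial
slice.  The result is a single 26-connected brain mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_nifti import CTVolume

#: 26-connectivity structuring element
_CONN26 = np.ones((3, 3, 3), dtype=bool)


class ExtractionError(RuntimeError):
    """Raised when no brain-like tissue can be found."""


@dataclass
class BrainMask:
    """A binary brain mask on a CT grid, with voxel bookkeeping."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cc(self) -> float:
        dx, dy, dz = self.spacing
        return self.voxel_count * dx * dy * dz / 1000.0


def _mm_ball(radius_mm: float, spacing) -> np.ndarray | None:
    """Ellipsoidal structuring element of physical radius ``radius_mm``.

    Returns None when the radius is below one voxel on every axis (no-op).
    """
    if radius_mm <= 0:
        return None
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    if all(h == 0 for h in half):
        return None
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    return sum(g ** 2 for g in grids) <= radius_mm ** 2


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        raise ExtractionError("no connected component found")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == np.argmax(counts)


def extract_brain(
    vol: CTVolume,
    hu_low: float = 0.0,
    hu_high: float = 50.0,
    erosion_mm: float = 2.0,
    dilation_mm: float = 2.0,
) -> BrainMask:
    """Extract the brain from a head CT.

    Candidate voxels satisfy ``hu_low <= HU < hu_high`` (the 50 HU upper
    bound removes skull and bone; the lower bound removes air).  The
    candidate set is eroded by ``erosion_mm``, the largest 26-connected
    component kept, dilated back by ``dilation_mm``, re-intersected with the
    candidate set, and hole-filled slice by axial slice.

    Raises
    ------
    ExtractionError
        If the candidate set is empty.
    """
    if hu_low >= hu_high:
        raise ValueError(f"need hu_low < hu_high, got {hu_low} >= {hu_high}")
    data = vol.data
    candidate = (data >= hu_low) & (data < hu_high)
    if not candidate.any():
        raise ExtractionError("no voxels in the brain HU window")

    se_e = _mm_ball(erosion_mm, vol.spacing)
    core = ndimage.binary_erosion(candidate, structure=se_e) if se_e is not None else candidate
    if not core.any():
        core = candidate  # erosion removed everything; fall back
    core = _largest_component(core)

    se_d = _mm_ball(dilation_mm, vol.spacing)
    if se_d is not None:
        core = ndimage.binary_dilation(core, structure=se_d)
    mask = core & candidate

    # slice-wise hole filling: 5 mm slices make 3D filling unreliable
    for k in range(mask.shape[2]):
        mask[:, :, k] = ndimage.binary_fill_holes(mask[:, :, k])
    # filling may have re-admitted above-threshold voxels; drop them and
    # keep a single component so the BrainMask invariants hold
    mask &= data < hu_high
    mask = _largest_component(mask)

    bm = BrainMask(mask, vol.spacing)
    if bm.volume_cc < 100.0:
        bm.warnings.append(
            f"extracted brain volume {bm.volume_cc:.1f} cc is implausibly small"
        )
    return bm
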