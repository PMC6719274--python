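"""NIfTI-1 input/output for head CT volumes in Hounsfield units.

Volumes are represented by :class:`CTVolume`, a light container around a 3D
float32 grid in HU with voxel spacing in mm and anatomical axis codes.  On
read, images are reoriented to the canonical RAS+ layout so that grid axis 0
is always the left-right axis; the hemisphere split downstream is then a
fixed-axis operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

HU_MIN = -1100.0
HU_MAX = 3200.0

#: axis codes of the internal canonical orientation (RAS+): index increases
#: toward the patient's Right, Anterior, Superior.
CANONICAL_AXCODES = ("R", "A", "S")


class FormatError(ValueError):
    """Raised for images that are not scalar 3D NIfTI-1."""


class OrientationError(ValueError):
    """Raised when the orientation metadata is missing or degenerate."""


@dataclass
class CTVolume:
    """A 3D CT volume in Hounsfield units.

    Parameters
    ----------
    data : ndarray
        3D float32 grid of HU values.
    spacing : tuple of float
        Voxel spacing (dx, dy, dz) in mm, all strictly positive.
    axis_codes : tuple of str
        Anatomical direction label for each grid axis (e.g. ``("R","A","S")``);
        exactly one axis must be the left-right axis (code ``L`` or ``R``).
    origin : tuple of float
        World-space offset of voxel (0,0,0) in mm (informational).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    axis_codes: tuple[str, str, str] = CANONICAL_AXCODES
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3D grid, got {self.data.ndim}D")
        # NIfTI-1 stores pixdim as float32; normalising here makes write/read
        # round-trips exact
        self.spacing = tuple(float(np.float32(s)) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.axis_codes = tuple(self.axis_codes)
        if sum(c in ("L", "R") for c in self.axis_codes) != 1:
            raise OrientationError(
                f"exactly one axis must be left-right, got {self.axis_codes}"
            )
        self.origin = tuple(float(o) for o in self.origin)

    def validate_hu(self) -> None:
        """Check HU plausibility (finite, within the CT dynamic range)."""
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(
                f"HU values [{lo:.1f}, {hi:.1f}] outside plausible CT range "
                f"[{HU_MIN}, {HU_MAX}]"
            )

    @property
    def lr_axis(self) -> int:
        """Index of the grid axis running left-right."""
        for i, c in enumerate(self.axis_codes):
            if c in ("L", "R"):
                return i
        raise OrientationError("no left-right axis")  # unreachable after init

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def copy(self) -> "CTVolume":
        return CTVolume(self.data.copy(), self.spacing, self.axis_codes, self.origin)

    def flipped_lr(self) -> "CTVolume":
        """Mirror image of the volume about the left-right axis."""
        ax = self.lr_axis
        return CTVolume(
            np.flip(self.data, axis=ax).copy(), self.spacing, self.axis_codes, self.origin
        )


def _canonical_affine(vol: CTVolume) -> np.ndarray:
    aff = np.diag(list(vol.spacing) + [1.0])
    aff[:3, 3] = vol.origin
    return aff


def read_volume(path) -> CTVolume:
    """Read a scalar 3D NIfTI-1 image as a :class:`CTVolume` in HU.

    The NIfTI scale slope/intercept are applied, and the image is reoriented
    to RAS+ so axis 0 is the left-right axis.

    Raises
    ------
    FormatError
        If the image is not 3D scalar.
    OrientationError
        If the affine is missing or degenerate.
    """
    img = nib.load(str(path))
    shape = img.header.get_data_shape()
    if len(shape) == 4 and shape[3] == 1:
        pass  # tolerate trailing singleton
    elif len(shape) != 3:
        raise FormatError(f"{path}: expected 3D scalar image, got shape {shape}")
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)) or np.linalg.det(affine[:3, :3]) == 0:
        raise OrientationError(f"{path}: missing or degenerate orientation affine")
    try:
        img = nib.as_closest_canonical(img)
    except Exception as exc:  # pragma: no cover - nibabel raises rarely here
        raise OrientationError(f"{path}: cannot reorient to canonical axes: {exc}") from exc
    data = np.asanyarray(img.get_fdata(dtype=np.float32))
    if data.ndim == 4:
        data = data[..., 0]
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    origin = tuple(float(x) for x in aff[:3, 3])
    axcodes = nib.orientations.aff2axcodes(aff)
    return CTVolume(data, spacing, tuple(axcodes), origin)


def write_volume(vol: CTVolume, path) -> None:
    """Write a :class:`CTVolume` as float32 NIfTI-1 (.nii or .nii.gz)."""
    if tuple(vol.axis_codes) != CANONICAL_AXCODES:
        raise OrientationError(
            f"only canonical {CANONICAL_AXCODES} volumes are written, got {vol.axis_codes}"
        )
    img = nib.Nifti1Image(vol.data.astype(np.float32), _canonical_affine(vol))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, like: CTVolume, path) -> None:
    """Write a binary grid as uint8 NIfTI-1 on the grid of ``like``."""
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _canonical_affine(like))
    img.header.set_zooms(like.spacing)
    nib.save(img, str(path))
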