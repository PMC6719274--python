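"""Synthetic head-CT phantom with hypodense lesions of known volume.

The phantom emulates the features of a noncontrast head CT that the
volumetry pipeline interacts with: an air background (~-1000 HU), a
high-attenuation skull shell, a uniform brain compartment around 34 HU, a
smooth left-right symmetric "cupping" depression of the HU toward the brain
centre (the dominant beam-hardening inhomogeneity in head CT), and additive
Gaussian noise.  Hypodense lesions (synthetic infarcts) are inserted with an
exactly known voxel-count volume and a fractional radiodensity reduction
``f`` relative to the clean tissue value, so the measured infarct volume can
be compared with truth.

Geometry uses a voxel-centre inclusion rule: a voxel belongs to a shape iff
its centre does, which makes the true lesion volume an exact voxel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_nifti import CANONICAL_AXCODES, CTVolume


class GeometryError(ValueError):
    """Raised when a phantom or lesion does not fit where it must."""


@dataclass
class PhantomSpec:
    """Parameters of the synthetic head.

    Defaults reproduce a 24 cm field of view at a 128 matrix with 5 mm
    slices: identical physical extent to the clinical 512-matrix protocol at
    desk-scale cost (volumes in cc do not depend on the matrix).
    """

    grid: tuple[int, int, int] = (128, 128, 30)
    spacing: tuple[float, float, float] = (1.875, 1.875, 5.0)
    hu_air: float = -1000.0
    hu_brain: float = 34.0
    hu_skull: float = 800.0
    brain_semiaxes: tuple[float, float, float] = (70.0, 85.0, 60.0)  # mm
    skull_thickness: float = 6.0  # mm
    cupping_amplitude: float = 3.0  # HU depression at the brain centroid
    noise_sigma: float = 2.0  # HU
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.hu_skull > 50 > self.hu_brain > self.hu_air):
            raise ValueError(
                "need hu_skull > 50 > hu_brain > hu_air, got "
                f"{self.hu_skull}, {self.hu_brain}, {self.hu_air}"
            )
        if self.cupping_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("cupping_amplitude and noise_sigma must be >= 0")
        half_extent = [n * s / 2.0 for n, s in zip(self.grid, self.spacing)]
        for a, h in zip(self.brain_semiaxes, half_extent):
            if a + self.skull_thickness >= h:
                raise GeometryError(
                    f"brain semiaxes {self.brain_semiaxes} + skull "
                    f"{self.skull_thickness} mm exceed grid half-extent {half_extent}"
                )

    @property
    def center_mm(self) -> tuple[float, float, float]:
        """Voxel-centre coordinates (mm) of the grid centre = brain centre."""
        return tuple((n - 1) / 2.0 * s for n, s in zip(self.grid, self.spacing))


@dataclass
class LesionSpec:
    """A hypodense lesion: a sphere of given true volume, or an angular
    wedge of the brain ellipsoid standing in for an arterial territory.

    ``density_reduction`` is the fraction f by which the clean tissue HU is
    reduced (0.05 ... 0.30 in the recovery study); the HU delta is
    ``-f * hu_brain``.
    """

    shape: str = "sphere"  # sphere | territory_wedge
    center: tuple[float, float, float] | None = None  # mm; wedge may omit
    target_volume_cc: float = 45.0
    wedge_angle_deg: float = 90.0  # full azimuthal width of the wedge
    density_reduction: float = 0.20
    side: str = "right"

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "territory_wedge"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")
        if not (0.0 < self.density_reduction <= 0.5):
            raise ValueError(
                f"density_reduction must lie in (0, 0.5], got {self.density_reduction}"
            )
        if self.shape == "sphere" and self.target_volume_cc <= 0:
            raise ValueError("target_volume_cc must be > 0")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass
class PhantomTruth:
    """A generated phantom together with its ground truth."""

    image: CTVolume
    brain_mask_true: np.ndarray
    lesion_mask_true: np.ndarray
    lesion_volume_true: float  # cc
    lesion_delta_hu: float  # magnitude f * hu_brain of the density reduction
    spec: PhantomSpec
    inhomogeneity_true: np.ndarray = field(default=None, repr=False)  # applied cupping, HU

    @property
    def clean_image(self) -> np.ndarray:
        """The image with the applied inhomogeneity removed (noise kept)."""
        return self.image.data - self.inhomogeneity_true


def sphere_radius_from_volume(v_cc: float) -> float:
    """Radius in mm of a sphere of volume ``v_cc`` cc."""
    if v_cc <= 0:
        raise ValueError(f"volume must be positive, got {v_cc}")
    return float((3.0 * 1000.0 * v_cc / (4.0 * np.pi)) ** (1.0 / 3.0))


def _coords_mm(spec: PhantomSpec):
    """Voxel-centre coordinate arrays (mm), broadcastable to the grid."""
    axes = [
        (np.arange(n, dtype=np.float64) * s).reshape(
            [-1 if k == i else 1 for k in range(3)]
        )
        for i, (n, s) in enumerate(zip(spec.grid, spec.spacing))
    ]
    return axes


def _ellipsoid_rho2(spec: PhantomSpec, semiaxes) -> np.ndarray:
    x, y, z = _coords_mm(spec)
    cx, cy, cz = spec.center_mm
    ax, ay, az = semiaxes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2


def make_head_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate a lesion-free synthetic head CT.

    The brain is an ellipsoid of uniform ``hu_brain`` inside a skull shell
    inside air.  A radially quadratic cupping field is added inside the
    brain only: ``-cupping_amplitude`` at the centroid, 0 at the brain edge.
    Seeded i.i.d. Gaussian noise is added everywhere; the noise realisation
    depends only on ``(grid, noise_sigma, seed)``, so phantoms differing
    only in cupping amplitude share their noise voxel for voxel.
    """
    rho2 = _ellipsoid_rho2(spec, spec.brain_semiaxes)
    outer = tuple(a + spec.skull_thickness for a in spec.brain_semiaxes)
    rho2_outer = _ellipsoid_rho2(spec, outer)

    brain = rho2 <= 1.0
    skull = (rho2_outer <= 1.0) & ~brain

    img = np.full(spec.grid, spec.hu_air, dtype=np.float64)
    img[skull] = spec.hu_skull
    img[brain] = spec.hu_brain

    cupping = np.zeros(spec.grid, dtype=np.float64)
    if spec.cupping_amplitude > 0:
        cupping[brain] = -spec.cupping_amplitude * (1.0 - rho2[brain])
    img += cupping

    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, 1.0, size=spec.grid)  # drawn regardless of sigma
    if spec.noise_sigma > 0:
        img += spec.noise_sigma * noise

    vol = CTVolume(img.astype(np.float32), spec.spacing, CANONICAL_AXCODES)
    return PhantomTruth(
        image=vol,
        brain_mask_true=brain,
        lesion_mask_true=np.zeros(spec.grid, dtype=bool),
        lesion_volume_true=0.0,
        lesion_delta_hu=0.0,
        spec=spec,
        inhomogeneity_true=cupping.astype(np.float32),
    )


def default_lesion_center(spec: PhantomSpec, side: str = "right", offset_mm: float = 35.0):
    """A lesion centre ``offset_mm`` lateral of the brain centre on ``side``.

    At the default geometry this keeps every sphere of the recovery study
    (17-122 cc) inside one hemisphere of the brain ellipsoid.
    """
    cx, cy, cz = spec.center_mm
    sign = 1.0 if side == "right" else -1.0  # +x is patient right in RAS
    return (cx + sign * offset_mm, cy, cz)


def _lesion_geometry_mask(spec: PhantomSpec, lesion: LesionSpec) -> np.ndarray:
    x, y, z = _coords_mm(spec)
    if lesion.shape == "sphere":
        if lesion.center is None:
            raise ValueError("sphere lesion requires an explicit center")
        r = sphere_radius_from_volume(lesion.target_volume_cc)
        cx, cy, cz = lesion.center
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r * r
    # territory_wedge: azimuthal sector of the brain ellipsoid about the
    # vertical (z) axis, pointing laterally on the requested side
    cx, cy, cz = spec.center_mm
    phi0 = 0.0 if lesion.side == "right" else np.pi
    half = np.deg2rad(lesion.wedge_angle_deg) / 2.0
    if half <= 0 or half > np.pi / 2:
        raise ValueError("wedge_angle_deg must lie in (0, 180]")
    phi = np.arctan2(y - cy, x - cx)
    dphi = np.abs(np.angle(np.exp(1j * (phi - phi0))))
    inside = _ellipsoid_rho2(spec, spec.brain_semiaxes) <= 1.0
    return inside & (dphi <= half) & (np.abs(x - cx) > 0)


def _check_side(mask: np.ndarray, spec: PhantomSpec, side: str) -> None:
    cx = spec.center_mm[0]
    x_idx = np.nonzero(mask)[0]
    x_mm = x_idx * spec.spacing[0]
    if side == "right" and np.any(x_mm <= cx):
        raise GeometryError("lesion crosses the midline onto the left side")
    if side == "left" and np.any(x_mm >= cx):
        raise GeometryError("lesion crosses the midline onto the right side")


def insert_lesion(truth: PhantomTruth, lesion: LesionSpec) -> PhantomTruth:
    """Insert a hypodense lesion into an existing phantom.

    HU inside the lesion are reduced by ``f * hu_brain`` (the reduction is
    defined against the clean tissue value, applied as an additive delta on
    the existing image, i.e. commuting with cupping and noise).  Ground
    truth masks and volume are updated; the returned truth is a new object.
    """
    spec = truth.spec
    geom = _lesion_geometry_mask(spec, lesion)
    if not geom.any():
        raise GeometryError("lesion geometry contains no voxel centres")
    if not np.all(truth.brain_mask_true[geom]):
        raise GeometryError("lesion extends outside the brain")
    _check_side(geom, spec, lesion.side)

    delta = lesion.density_reduction * spec.hu_brain
    img = truth.image.data.astype(np.float64)
    img[geom] -= delta
    new_mask = truth.lesion_mask_true | geom
    vol_cc = float(new_mask.sum()) * truth.image.voxel_volume_mm3 / 1000.0
    return replace(
        truth,
        image=CTVolume(
            img.astype(np.float32), truth.image.spacing, truth.image.axis_codes,
            truth.image.origin,
        ),
        lesion_mask_true=new_mask,
        lesion_volume_true=vol_cc,
        lesion_delta_hu=float(delta),
    )


def insert_territory_lesion(truth: PhantomTruth, lesion: LesionSpec) -> PhantomTruth:
    """Insert a territory-wedge lesion (see :class:`LesionSpec`)."""
    if lesion.shape != "territory_wedge":
        lesion = replace(lesion, shape="territory_wedge")
    return insert_lesion(truth, lesion)
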