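"""Synthetic multi-lesion PET phantoms with ground truth.

A phantom is a uniform background with ellipsoidal lesions of uniform
uptake, additive Gaussian noise, and an optional isotropic Gaussian PSF
blur (specified by its FWHM in mm).  Ground-truth masks are the pre-blur
ellipsoid voxelizations — a voxel belongs to a lesion iff its center lies
inside the ellipsoid — so the partial-volume bias of any delineator can be
measured against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .lesions import Lesion, LesionSet, PETVolume, PRIMARY, NODE

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class LesionSpec:
    """One ellipsoidal lesion: center and semi-axes in mm, uniform uptake."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    peak_suv: float
    role: str = PRIMARY


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_suv: float = 1.0
    noise_sd: float = 0.0
    psf_fwhm_mm: float = 0.0
    lesions: list[LesionSpec] = field(default_factory=list)
    rng_seed: int = 0

    def validate(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ConfigError("grid_shape must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigError("voxel sizes must be strictly positive")
        if self.background_suv <= 0:
            raise ConfigError("background_suv must be > 0")
        if self.noise_sd < 0 or self.psf_fwhm_mm < 0:
            raise ConfigError("noise_sd and psf_fwhm_mm must be >= 0")
        n_primary = sum(1 for l in self.lesions if l.role == PRIMARY)
        if self.lesions and n_primary != 1:
            raise ConfigError(
                f"exactly one lesion must have role 'primary' (got {n_primary})"
            )
        extent = [n * v for n, v in zip(self.grid_shape, self.voxel_size_mm)]
        for i, les in enumerate(self.lesions):
            if les.role not in (PRIMARY, NODE):
                raise ConfigError(f"lesion {i}: unknown role {les.role!r}")
            if any(r <= 0 for r in les.radii_mm):
                raise ConfigError(f"lesion {i}: radii must be > 0")
            for c, r, e in zip(les.center_mm, les.radii_mm, extent):
                if c - r < 0 or c + r > e:
                    raise ConfigError(
                        f"lesion {i} does not lie fully inside the grid "
                        f"(extent {extent} mm)"
                    )


@dataclass
class GroundTruthLesion:
    """True (pre-blur, pre-noise) properties of one phantom lesion."""

    role: str
    volume_ml: float  # voxelized volume: voxel count x voxel volume
    mean_suv: float
    max_suv: float


@dataclass
class PhantomGroundTruth:
    lesions: list[GroundTruthLesion]


def _ellipsoid_mask(shape, voxel_size, center_mm, radii_mm) -> np.ndarray:
    """Voxel centers inside the ellipsoid."""
    coords = [
        (np.arange(n) + 0.5) * v for n, v in zip(shape, voxel_size)
    ]
    xx = ((coords[0] - center_mm[0]) / radii_mm[0]) ** 2
    yy = ((coords[1] - center_mm[1]) / radii_mm[1]) ** 2
    zz = ((coords[2] - center_mm[2]) / radii_mm[2]) ** 2
    return (
        xx[:, None, None] + yy[None, :, None] + zz[None, None, :]
    ) <= 1.0


def generate_phantom(
    config: PhantomConfig,
) -> tuple[PETVolume, LesionSet, PhantomGroundTruth]:
    """Build a phantom volume, its ground-truth lesion masks, and truth table.

    The image is ``background_suv`` everywhere, each ellipsoid set to its
    ``peak_suv``, then Gaussian noise is added and finally the optional PSF
    blur applied.  Deterministic under a fixed ``rng_seed``.
    """
    config.validate()
    shape = tuple(int(n) for n in config.grid_shape)
    voxel_size = tuple(float(v) for v in config.voxel_size_mm)
    values = np.full(shape, config.background_suv, dtype=float)

    lesions: list[Lesion] = []
    truths: list[GroundTruthLesion] = []
    voxel_ml = float(np.prod(voxel_size)) / 1000.0
    for spec in config.lesions:
        mask = _ellipsoid_mask(shape, voxel_size, spec.center_mm, spec.radii_mm)
        if not mask.any():
            raise ConfigError(
                f"lesion at {spec.center_mm} mm contains no voxel center "
                f"(radii {spec.radii_mm} mm below grid resolution)"
            )
        values[mask] = spec.peak_suv
        lesions.append(Lesion(mask=mask, role=spec.role))
        truths.append(
            GroundTruthLesion(
                role=spec.role,
                volume_ml=int(mask.sum()) * voxel_ml,
                mean_suv=spec.peak_suv,
                max_suv=spec.peak_suv,
            )
        )

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.rng_seed)
        values = values + rng.normal(0.0, config.noise_sd, size=shape)
    if config.psf_fwhm_mm > 0:
        sigma_vox = [
            config.psf_fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size
        ]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)

    volume = PETVolume(values=values, voxel_size=voxel_size)
    return volume, LesionSet(lesions), PhantomGroundTruth(truths)
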