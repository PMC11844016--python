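"""Lesion delineation and quantitative PET parameters.

The imaging substrate is a 3D grid of standardized uptake values (SUV).
Lesions (one primary tumor plus any number of PET-positive lymph nodes)
are represented as labeled voxel masks.  From each mask the four standard
quantitative parameters are computed:

* ``suv_max``  — maximum SUV over the mask,
* ``suv_mean`` — arithmetic mean SUV over the mask,
* ``mtv``      — metabolic tumor volume: voxel count x voxel volume, in ml,
* ``tlg``      — total lesion glycolysis: MTV x SUV_mean.

Per-patient parameters come in two flavors: ``_prim`` (primary tumor only)
and ``_all`` (primary plus all nodes), where SUV_all is the overall SUV_max,
MTV_all the cumulative volume, and TLG_all the volume-weighted overall
SUV_mean times MTV_all — which makes TLG additive over disjoint lesions.

Delineation uses background-adaptive thresholding: the lesion boundary is
placed at ``T = BG + beta * (lesion_max - BG)`` with the local background BG
estimated on a shell around the current region, iterated to convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, ConvergenceError, NoLesionAtSeedError

#: 3x3x3 structuring element: 26-connectivity (faces, edges, corners).
CONN26 = np.ones((3, 3, 3), dtype=bool)

PRIMARY = "primary"
NODE = "node"


@dataclass
class PETVolume:
    """A 3D SUV image with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values in SUV (g/ml convention, unitless).
    voxel_size : tuple of float
        Spacing per axis in mm.  Voxel ``(i, j, k)`` is centered at
        ``((i + 0.5) * dx, (j + 0.5) * dy, (k + 0.5) * dz)``.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ConfigError("PETVolume.values must be 3-dimensional")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ConfigError("voxel_size must be three strictly positive mm values")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("PETVolume contains non-finite values")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (= mm^3 / 1000)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    def mm_to_index(self, position_mm) -> tuple[int, int, int]:
        """Voxel index whose cell contains the physical point (mm)."""
        idx = tuple(int(np.floor(p / s)) for p, s in zip(position_mm, self.voxel_size))
        if any(i < 0 or i >= n for i, n in zip(idx, self.values.shape)):
            raise ConfigError(f"position {tuple(position_mm)} mm is outside the grid")
        return idx


@dataclass
class Lesion:
    """A single lesion: boolean voxel mask plus its role."""

    mask: np.ndarray
    role: str  # "primary" | "node"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.role not in (PRIMARY, NODE):
            raise ConfigError(f"unknown lesion role {self.role!r}")
        if not self.mask.any():
            raise ConfigError("lesion mask is empty")


@dataclass
class LesionSet:
    """All lesions of one patient; masks are pairwise voxel-disjoint."""

    lesions: list[Lesion] = field(default_factory=list)

    def __post_init__(self):
        if len(self.lesions) > 1:
            acc = np.zeros(self.lesions[0].mask.shape, dtype=int)
            for les in self.lesions:
                acc += les.mask
            if acc.max() > 1:
                raise ConfigError("lesion masks overlap")

    def __len__(self):
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)

    @property
    def primary(self) -> Lesion | None:
        for les in self.lesions:
            if les.role == PRIMARY:
                return les
        return None

    @property
    def nodes(self) -> list[Lesion]:
        return [les for les in self.lesions if les.role == NODE]

    def label_array(self, shape=None) -> np.ndarray:
        """Integer label image: 0 background, 1 primary, >= 2 nodes."""
        if shape is None:
            if not self.lesions:
                raise ConfigError("label_array of an empty LesionSet needs a shape")
            shape = self.lesions[0].mask.shape
        out = np.zeros(shape, dtype=np.int16)
        label = 2
        for les in self.lesions:
            if les.role == PRIMARY:
                out[les.mask] = 1
            else:
                out[les.mask] = label
                label += 1
        return out

    @classmethod
    def from_label_array(cls, labels: np.ndarray) -> "LesionSet":
        labels = np.asarray(labels)
        lesions = []
        for lab in np.unique(labels):
            if lab == 0:
                continue
            role = PRIMARY if lab == 1 else NODE
            lesions.append(Lesion(mask=labels == lab, role=role))
        return cls(lesions)


@dataclass
class DelineationConfig:
    """Parameters of the background-adaptive threshold delineator.

    ``threshold_fraction`` is the fraction beta of the background-corrected
    lesion maximum at which the boundary is placed; 0.39 is the standard
    default for FDG lesions.  The local background is the mean SUV over a
    shell around the current region, separated by ``shell_gap`` voxels and
    ``shell_thickness`` voxels thick.
    """

    threshold_fraction: float = 0.39
    shell_gap: int = 1
    shell_thickness: int = 2
    max_iterations: int = 50
    convergence_tol: float = 1e-3  # relative volume change

    def __post_init__(self):
        if not 0 < self.threshold_fraction < 1:
            raise ConfigError("threshold_fraction must be in (0, 1)")
        if self.shell_thickness < 1:
            raise ConfigError("shell_thickness must be >= 1 voxel")
        if self.shell_gap < 0:
            raise ConfigError("shell_gap must be >= 0 voxels")


@dataclass
class LesionMetrics:
    """Quantitative parameters of a single lesion."""

    suv_max: float
    suv_mean: float
    mtv: float  # ml
    tlg: float  # MTV x SUV_mean; reported in "ml" by field convention


@dataclass
class PatientPETParams:
    """The six per-patient parameters: primary-only and primary+nodes."""

    suv_prim: float
    mtv_prim: float
    tlg_prim: float
    suv_all: float
    mtv_all: float
    tlg_all: float


@dataclass
class Seed:
    """A delineation seed: physical position (mm) and the lesion role."""

    position_mm: tuple[float, float, float]
    role: str = PRIMARY


def compute_lesion_metrics(volume: PETVolume, mask: np.ndarray) -> LesionMetrics:
    """Compute SUV_max, SUV_mean, MTV and TLG over a voxel mask.

    MTV is the voxel count times the voxel volume in ml; TLG = MTV x SUV_mean.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.values.shape:
        raise ConfigError("mask shape does not match volume shape")
    n = int(mask.sum())
    if n == 0:
        raise ConfigError("cannot compute metrics on an empty mask")
    vals = volume.values[mask]
    mtv = n * volume.voxel_volume_ml
    suv_mean = float(vals.mean())
    return LesionMetrics(
        suv_max=float(vals.max()),
        suv_mean=suv_mean,
        mtv=mtv,
        tlg=mtv * suv_mean,
    )


def aggregate_patient(
    primary: LesionMetrics, nodes: list[LesionMetrics]
) -> PatientPETParams:
    """Combine primary-tumor and nodal metrics into the six patient parameters.

    SUV_all is the overall SUV_max, MTV_all the cumulative volume, and the
    overall SUV_mean is volume-weighted so that
    ``TLG_all = overall_SUV_mean * MTV_all = sum of per-lesion TLG``.
    """
    if primary is None:
        raise ConfigError("a patient needs exactly one primary lesion")
    all_metrics = [primary, *nodes]
    mtv_all = sum(m.mtv for m in all_metrics)
    mean_all = sum(m.suv_mean * m.mtv for m in all_metrics) / mtv_all
    return PatientPETParams(
        suv_prim=primary.suv_max,
        mtv_prim=primary.mtv,
        tlg_prim=primary.tlg,
        suv_all=max(m.suv_max for m in all_metrics),
        mtv_all=mtv_all,
        tlg_all=mean_all * mtv_all,
    )


def patient_params_from_lesions(
    volume: PETVolume, lesions: LesionSet
) -> PatientPETParams:
    """Convenience: per-lesion metrics + aggregation in one call."""
    primary = lesions.primary
    if primary is None:
        raise ConfigError("LesionSet has no primary lesion")
    prim_m = compute_lesion_metrics(volume, primary.mask)
    node_m = [compute_lesion_metrics(volume, les.mask) for les in lesions.nodes]
    return aggregate_patient(prim_m, node_m)


def _shell_mean(
    values: np.ndarray,
    mask: np.ndarray,
    exclude: np.ndarray | None,
    gap: int,
    thickness: int,
) -> float:
    """Mean over a shell around ``mask``: ``gap`` voxels away, ``thickness``

    voxels thick, excluding ``exclude`` voxels (other lesions)."""
    inner = ndimage.binary_dilation(mask, CONN26, iterations=gap) if gap else mask
    outer = ndimage.binary_dilation(inner, CONN26, iterations=thickness)
    shell = outer & ~inner
    if exclude is not None:
        shell &= ~exclude
    if not shell.any():  # lesion fills the grid; fall back to global complement
        shell = ~mask if exclude is None else ~(mask | exclude)
        if not shell.any():
            return 0.0
    return float(values[shell].mean())


def _delineate_one(
    volume: PETVolume,
    seed_idx: tuple[int, int, int],
    config: DelineationConfig,
    exclude: np.ndarray | None,
) -> np.ndarray:
    values = volume.values
    mask = np.zeros(values.shape, dtype=bool)
    mask[seed_idx] = True
    prev_n = 1
    volumes = [volume.voxel_volume_ml]
    for it in range(config.max_iterations):
        lesion_max = float(values[mask].max())
        if it == 0:
            # the 1-voxel seed mask has no meaningful local shell yet; the
            # global median is a robust first background estimate (lesions
            # occupy a small fraction of the field of view)
            bg = float(np.median(values))
        else:
            bg = _shell_mean(
                values, mask, exclude, config.shell_gap, config.shell_thickness
            )
        if it == 0 and values[seed_idx] <= bg:
            raise NoLesionAtSeedError(
                f"seed {seed_idx} (SUV {values[seed_idx]:.3g}) is not above "
                f"its local background ({bg:.3g})"
            )
        thresh = bg + config.threshold_fraction * (lesion_max - bg)
        above = values >= thresh
        if exclude is not None:
            above &= ~exclude
        if not above[seed_idx]:
            if it == 0:
                raise NoLesionAtSeedError(
                    f"seed {seed_idx} (SUV {values[seed_idx]:.3g}) is below the "
                    f"adaptive threshold {thresh:.3g} (background {bg:.3g})"
                )
            # threshold climbed above the seed: keep the last converged mask
            break
        labels, _ = ndimage.label(above, structure=CONN26)
        new_mask = labels == labels[seed_idx]
        n = int(new_mask.sum())
        volumes.append(n * volume.voxel_volume_ml)
        rel_change = abs(n - prev_n) / max(prev_n, 1)
        mask = new_mask
        if it > 0 and rel_change < config.convergence_tol:
            return mask
        prev_n = n
    else:
        raise ConvergenceError(
            f"delineation did not converge within {config.max_iterations} "
            f"iterations (last volumes {volumes[-2]:.4g}, {volumes[-1]:.4g} ml)",
            history=(volumes[-2], volumes[-1]),
        )
    return mask


def delineate_adaptive(
    volume: PETVolume,
    seeds: list[Seed],
    config: DelineationConfig | None = None,
) -> LesionSet:
    """Delineate lesions by iterative background-adaptive thresholding.

    For each seed the region is grown 26-connectedly above the threshold
    ``T = BG + beta * (lesion_max - BG)``, with BG re-estimated each
    iteration on a shell around the current region (voxels of previously
    delineated lesions are excluded from shells and regions).  Iteration
    stops when the relative volume change falls below ``convergence_tol``.
    Masks of distinct seeds that collide are merged into a single lesion;
    the first seed's role wins.

    Raises
    ------
    NoLesionAtSeedError
        If a seed lies below the adaptive threshold at the first iteration.
    ConvergenceError
        If the region does not stabilize within ``max_iterations``.
    """
    if config is None:
        config = DelineationConfig()
    if not seeds:
        return LesionSet([])
    masks: list[np.ndarray] = []
    roles: list[str] = []
    occupied = np.zeros(volume.values.shape, dtype=bool)
    for seed in seeds:
        idx = volume.mm_to_index(seed.position_mm)
        if occupied[idx]:
            # seed falls inside an already-delineated lesion: same lesion,
            # the earlier seed's role wins
            for mask in masks:
                if mask[idx]:
                    break
            continue
        exclude = occupied if occupied.any() else None
        mask = _delineate_one(volume, idx, config, exclude)
        masks.append(mask)
        roles.append(seed.role)
        occupied |= mask

    # merge colliding masks (possible when exclusion did not separate them)
    merged: list[tuple[np.ndarray, str]] = []
    for mask, role in zip(masks, roles):
        for i, (m, r) in enumerate(merged):
            if (m & mask).any():
                merged[i] = (m | mask, r)  # earlier seed's role wins
                break
        else:
            merged.append((mask, role))
    return LesionSet([Lesion(mask=m, role=r) for m, r in merged])
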