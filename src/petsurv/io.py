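"""Readers, writers, and plotting shared by all pipeline stages.

Formats
-------
* Cohort tables: CSV with a schema-version comment line (``# petsurv-cohort-v1``),
  columns per :data:`petsurv.records.COHORT_COLUMNS`, times in months,
  volumes in ml, missing categoricals as ``"n/a"``.
* Volumes and label masks: NIfTI (``.nii`` / ``.nii.gz``), spacing taken
  from the header zooms; masks are integer-labeled (0 background, 1
  primary, >= 2 nodes).
* Seeds: CSV with columns x_mm, y_mm, z_mm, role.
* Configs: YAML mirroring the dataclass fields.

All writers are deterministic given identical inputs: stable row ordering
and fixed float formatting.
"""

from __future__ import annotations

import dataclasses
import io as _io
import pathlib

import matplotlib

matplotlib.use("Agg")  # headless, deterministic backend

import matplotlib.pyplot as plt
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig
from .cox import KMCurve
from .errors import CohortValidationError, ConfigError
from .lesions import DelineationConfig, PETVolume, Seed
from .phantom import LesionSpec, PhantomConfig
from .records import (
    COHORT_COLUMNS,
    NA,
    PatientRecord,
    cohort_frame,
    records_from_frame,
)

SCHEMA_LINE = "# petsurv-cohort-v1"
_FLOAT_FMT = "%.17g"  # round-trip exact for float64


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def write_cohort(records: list[PatientRecord], path) -> None:
    df = cohort_frame(records)
    buf = _io.StringIO()
    buf.write(SCHEMA_LINE + "\n")
    df.to_csv(buf, index=False, float_format=_FLOAT_FMT, na_rep=NA)
    pathlib.Path(path).write_text(buf.getvalue())


def read_cohort(path) -> list[PatientRecord]:
    """Read and validate a cohort CSV; errors name the offending data row."""
    path = pathlib.Path(path)
    if not path.exists():
        raise CohortValidationError(f"no such file: {path}")
    with open(path) as fh:
        first = fh.readline().strip()
    skip = 1 if first.startswith("#") else 0
    df = pd.read_csv(
        path,
        skiprows=skip,
        na_values=[NA],
        keep_default_na=True,
        float_precision="round_trip",
    )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing columns: {missing}")
    df = df[COHORT_COLUMNS]
    for col in ("sex", "t_stage", "n_stage", "uicc_stage", "chemo", "hpv"):
        df[col] = df[col].fillna(NA)
    records = records_from_frame(df)
    for i, rec in enumerate(records):
        rec.validate(row=i)
    return records


# ---------------------------------------------------------------------------
# NIfTI volumes and masks
# ---------------------------------------------------------------------------

def write_volume(volume: PETVolume, path) -> None:
    affine = np.diag([*volume.voxel_size, 1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float64), affine)
    img.header.set_zooms(volume.voxel_size)
    nib.save(img, str(path))


def read_volume(path) -> PETVolume:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PETVolume(values=np.asarray(img.dataobj, dtype=float), voxel_size=zooms)


def write_mask(labels: np.ndarray, voxel_size, path) -> None:
    affine = np.diag([*voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine)
    img.header.set_zooms(tuple(voxel_size))
    nib.save(img, str(path))


def read_mask(path, volume: PETVolume | None = None) -> np.ndarray:
    """Read an integer label mask; if ``volume`` is given, reject any grid

    or spacing mismatch between the two."""
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    if volume is not None:
        if labels.shape != volume.values.shape:
            raise ConfigError(
                f"mask grid {labels.shape} does not match volume grid "
                f"{volume.values.shape}"
            )
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        if not np.allclose(zooms, volume.voxel_size, rtol=1e-6):
            raise ConfigError(
                f"mask spacing {zooms} does not match volume spacing "
                f"{volume.voxel_size}"
            )
    return labels


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------

def write_seeds(seeds: list[Seed], path) -> None:
    df = pd.DataFrame(
        {
            "x_mm": [s.position_mm[0] for s in seeds],
            "y_mm": [s.position_mm[1] for s in seeds],
            "z_mm": [s.position_mm[2] for s in seeds],
            "role": [s.role for s in seeds],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_seeds(path) -> list[Seed]:
    df = pd.read_csv(path)
    return [
        Seed(position_mm=(r.x_mm, r.y_mm, r.z_mm), role=r.role)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# YAML configs
# ---------------------------------------------------------------------------

def load_phantom_config(path) -> PhantomConfig:
    data = yaml.safe_load(pathlib.Path(path).read_text())
    lesions = [LesionSpec(**l) for l in data.pop("lesions", [])]
    cfg = PhantomConfig(lesions=lesions, **data)
    cfg.validate()
    return cfg


def load_cohort_config(path) -> CohortConfig:
    data = yaml.safe_load(pathlib.Path(path).read_text())
    cfg = CohortConfig(**data)
    cfg.validate()
    return cfg


def save_config(config, path) -> None:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    pathlib.Path(path).write_text(
        yaml.safe_dump(clean(config), sort_keys=True)
    )


def load_delineation_config(path) -> DelineationConfig:
    data = yaml.safe_load(pathlib.Path(path).read_text())
    return DelineationConfig(**data)


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def render_km(
    curves: list[KMCurve],
    labels: list[str] | None = None,
    path=None,
    title: str = "",
    xlabel: str = "Time (months)",
):
    """Step plot of Kaplan-Meier curves with an at-risk annotation.

    Deterministic output for fixed inputs (Agg backend, fixed figure
    geometry, no timestamps in the file metadata for SVG).
    """
    if not curves:
        raise ConfigError("render_km needs at least one curve")
    if labels is None:
        labels = [c.label or f"group {i}" for i, c in enumerate(curves)]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for curve, label in zip(curves, labels):
        t = np.r_[0.0, curve.times]
        s = np.r_[1.0, curve.survival]
        ax.step(t, s, where="post", label=f"{label} (n={curve.n})")
    ax.set_ylim(0, 1.05)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("Survival probability")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower left", fontsize=8)
    at_risk = " | ".join(
        f"{lab}: n={c.n}, events={int(c.n_events.sum())}"
        for lab, c in zip(labels, curves)
    )
    fig.text(0.01, 0.01, f"at risk: {at_risk}", fontsize=7)
    fig.tight_layout(rect=(0, 0.04, 1, 1))
    if path is not None:
        fig.savefig(str(path), dpi=120, metadata=_plot_metadata(str(path)))
        plt.close(fig)
        return None
    return fig


def _plot_metadata(path: str):
    # strip volatile timestamps so identical inputs give identical bytes
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": "petsurv"}
    return None
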