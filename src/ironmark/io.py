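"""File formats: NIfTI volumes with echo-time sidecars, masks, transforms,
cohort CSVs and the pipeline configuration.

Conventions: NIfTI-1 throughout, axis-aligned affine ``diag(spacing)`` with
the origin at voxel (0, 0, 0); echo times live in a JSON sidecar
``<name>.echoes.json`` (NIfTI has no echo-time field).  CSV headers are
validated on read with explicit error messages.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .registration import RigidTransform
from .relaxometry import MultiEchoVolume, T2StarMap, RelaxometryConfig

__all__ = [
    "sidecar_path",
    "write_multiecho",
    "read_multiecho",
    "write_mask",
    "read_mask",
    "write_t2star_map",
    "read_t2star_map",
    "write_transform",
    "read_transform",
    "write_cohort",
    "read_cohort",
    "FormatError",
]

COHORT_COLUMNS = [
    "patient_id", "sex", "current_smoker", "sbp_mmhg", "baseline_diameter_mm",
    "true_enhanced", "observed_status", "true_growth_mm_per_yr",
    "event_time_days", "event", "event_type",
]
ULTRASOUND_COLUMNS = ["patient_id", "time_years", "diameter_mm"]


class FormatError(ValueError):
    pass


def _affine(spacing) -> np.ndarray:
    return np.diag([*spacing, 1.0])


def _spacing_of(img) -> tuple:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def sidecar_path(path) -> Path:
    """``pre.nii.gz`` -> ``pre.echoes.json``"""
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".echoes.json")
    return path.with_suffix(".echoes.json")


def write_multiecho(volume: MultiEchoVolume, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(
        volume.intensities.astype(np.float32), _affine(volume.voxel_spacing)
    )
    nib.save(img, path)
    sidecar_path(path).write_text(json.dumps(list(map(float, volume.echo_times))))
    return path


def read_multiecho(path, sidecar=None) -> MultiEchoVolume:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else sidecar_path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(
            f"{path}: expected a 4D (x, y, z, echo) volume, got {data.ndim}D"
        )
    if not sidecar.exists():
        raise FormatError(f"echo-time sidecar {sidecar} not found")
    echoes = np.asarray(json.loads(sidecar.read_text()), dtype=float)
    if echoes.size != data.shape[3]:
        raise FormatError(
            f"{path}: volume has {data.shape[3]} echoes but sidecar "
            f"{sidecar} lists {echoes.size} echo times"
        )
    if np.any(np.diff(echoes) <= 0):
        raise FormatError(f"{sidecar}: echo times must be strictly ascending")
    return MultiEchoVolume(data, echoes, _spacing_of(img))


def write_mask(mask: np.ndarray, path, spacing=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing)), path)
    return path


def read_mask(path) -> np.ndarray:
    img = nib.load(path)
    return np.asarray(img.dataobj) > 0


def write_t2star_map(t2map: T2StarMap, path) -> Path:
    """Writes four NIfTI files: ``<stem>`` (T2*, float32), plus
    ``.valid`` (uint8), ``.s0`` and ``.r2`` companions."""
    path = Path(path)
    aff = _affine(t2map.voxel_spacing)
    nib.save(nib.Nifti1Image(t2map.t2star.astype(np.float32), aff), path)
    for arr, tag, dtype in (
        (t2map.valid, "valid", np.uint8),
        (t2map.s0, "s0", np.float32),
        (t2map.r_squared, "r2", np.float32),
    ):
        nib.save(
            nib.Nifti1Image(np.asarray(arr, dtype=dtype), aff), _companion(path, tag)
        )
    return path


def _companion(path: Path, tag: str) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + f".{tag}{suffix}")
    return path.with_suffix(f".{tag}.nii")


def read_t2star_map(path) -> T2StarMap:
    path = Path(path)
    img = nib.load(path)
    t2 = np.asarray(img.dataobj, dtype=float)
    valid = np.asarray(nib.load(_companion(path, "valid")).dataobj) > 0
    s0 = np.asarray(nib.load(_companion(path, "s0")).dataobj, dtype=float)
    r2 = np.asarray(nib.load(_companion(path, "r2")).dataobj, dtype=float)
    t2 = np.where(valid, t2, np.nan)
    return T2StarMap(
        t2star=t2, s0=s0, r_squared=r2, valid=valid,
        voxel_spacing=_spacing_of(img), config=RelaxometryConfig(),
    )


def write_transform(transform: RigidTransform, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(transform.to_dict(), indent=2))
    return path


def read_transform(path) -> RigidTransform:
    return RigidTransform.from_dict(json.loads(Path(path).read_text()))


def write_cohort(cohort, out_dir) -> tuple[Path, Path]:
    """Writes ``cohort.csv`` (one row per patient) and ``ultrasound.csv``
    (long format) into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p1 = out_dir / "cohort.csv"
    p2 = out_dir / "ultrasound.csv"
    cohort.patients.to_csv(p1, index=False)
    cohort.ultrasound.to_csv(p2, index=False)
    return p1, p2


def read_cohort(cohort_csv, ultrasound_csv=None):
    from .synthetic import CohortTable

    patients = pd.read_csv(cohort_csv)
    missing = [c for c in COHORT_COLUMNS if c not in patients.columns]
    if missing:
        raise FormatError(
            f"{cohort_csv}: missing cohort columns {missing}; "
            f"expected header {COHORT_COLUMNS}"
        )
    if ultrasound_csv is None:
        ultrasound = pd.DataFrame(columns=ULTRASOUND_COLUMNS)
    else:
        ultrasound = pd.read_csv(ultrasound_csv)
        missing = [c for c in ULTRASOUND_COLUMNS if c not in ultrasound.columns]
        if missing:
            raise FormatError(
                f"{ultrasound_csv}: missing ultrasound columns {missing}; "
                f"expected header {ULTRASOUND_COLUMNS}"
            )
    return CohortTable(patients=patients, ultrasound=ultrasound)
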