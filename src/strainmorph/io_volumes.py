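"""NIfTI and CSV input/output for the pipeline's volumetric and tabular data.

Displacement fields are X*Y*Z*3 NIfTI volumes; tensor maps X*Y*Z*6 with
component order ``(xx, yy, zz, xy, yz, zx)``; scalar maps and label atlases
plain 3-D volumes.  All volumes are written in float64 (labels as int32) so
that write -> read round-trips are bit-exact.

NIfTI carries no convention for the units of a stored displacement field, so
:func:`read_displacement_field` takes an explicit ``units`` argument:
``"mm"`` (values are physical displacements, the package convention) or
``"voxel"`` (values are index offsets, converted to mm through the affine's
linear part at read time).
"""

from __future__ import annotations

import os
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import (
    TENSOR_COMPONENT_ORDER,
    DisplacementField,
    LabelAtlas,
    ScalarMap,
    TensorMap,
    VolumeGrid,
)

__all__ = [
    "read_displacement_field",
    "write_displacement_field",
    "read_scalar_map",
    "write_scalar_map",
    "read_tensor_map",
    "write_tensor_map",
    "read_mask",
    "write_mask",
    "read_label_atlas",
    "write_label_atlas",
    "read_cohort_table",
    "write_table",
    "COHORT_COLUMNS",
]

#: required columns of a cohort table, one row per (subject, interval)
COHORT_COLUMNS = ("subject_id", "interval_id", "days_between_scans", "midpoint_age_days")


def _load(path: str | os.PathLike) -> nib.Nifti1Image:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    return nib.load(str(path))


def _grid_of(img: nib.Nifti1Image) -> VolumeGrid:
    return VolumeGrid(tuple(int(s) for s in img.shape[:3]), np.asarray(img.affine))


def _save(path, data: np.ndarray, grid: VolumeGrid, dtype=np.float64) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), grid.affine)
    nib.save(img, str(path))


def read_displacement_field(
    path: str | os.PathLike,
    mask_path: str | os.PathLike | None = None,
    units: str = "mm",
) -> DisplacementField:
    """Read a 4-D vector NIfTI (X*Y*Z*3) as a displacement field.

    Parameters
    ----------
    path
        Vector image with exactly 3 values per voxel.
    mask_path
        Optional binary mask volume on the same grid; defaults to all
        finite-displacement voxels.
    units
        ``"mm"`` if stored values are physical displacements, ``"voxel"``
        if they are voxel-index offsets (converted via the affine).
    """
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError(
            f"displacement field must be X*Y*Z*3, got shape {data.shape}"
        )
    grid = _grid_of(img)
    if units == "voxel":
        data = data @ grid.affine[:3, :3].T
    elif units != "mm":
        raise ValueError(f"unknown displacement units {units!r} (use 'mm' or 'voxel')")

    finite = np.isfinite(data).all(axis=-1)
    if mask_path is not None:
        mask = read_mask(mask_path, grid)
        n_bad = int((mask & ~finite).sum())
        if n_bad:
            raise ValueError(
                f"displacement field has non-finite values at {n_bad} masked voxel(s)"
            )
    else:
        mask = finite
    return DisplacementField(grid, data, mask)


def write_displacement_field(path, field: DisplacementField) -> None:
    _save(path, field.u, field.grid)


def read_mask(path, grid: VolumeGrid | None = None) -> np.ndarray:
    img = _load(path)
    if grid is not None:
        grid.require_matches(_grid_of(img), "mask and data")
    return np.asarray(img.dataobj) > 0.5


def write_mask(path, mask: np.ndarray, grid: VolumeGrid) -> None:
    _save(path, mask.astype(np.uint8), grid, dtype=np.uint8)


def read_scalar_map(path, mask_path=None) -> ScalarMap:
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"scalar map must be 3-D, got shape {data.shape}")
    grid = _grid_of(img)
    mask = read_mask(mask_path, grid) if mask_path is not None else np.isfinite(data)
    return ScalarMap(grid, data, mask)


def write_scalar_map(path, m: ScalarMap) -> None:
    _save(path, m.values, m.grid)


def read_tensor_map(path, mask_path=None) -> TensorMap:
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 6:
        raise ValueError(
            f"tensor map must be X*Y*Z*6 in order {TENSOR_COMPONENT_ORDER}, "
            f"got shape {data.shape}"
        )
    grid = _grid_of(img)
    mask = read_mask(mask_path, grid) if mask_path is not None else np.isfinite(data).all(axis=-1)
    return TensorMap(grid, data, mask)


def write_tensor_map(path, m: TensorMap) -> None:
    _save(path, m.values, m.grid)


def read_label_atlas(path, names_path) -> LabelAtlas:
    """Read an integer ROI volume plus a label->name CSV (columns label,name)."""
    img = _load(path)
    labels = np.asarray(img.dataobj)
    names = read_label_names(names_path)
    return LabelAtlas(_grid_of(img), labels, names)


def read_label_names(names_path) -> dict[int, str]:
    df = pd.read_csv(names_path)
    if not {"label", "name"} <= set(df.columns):
        raise ValueError("names file must have columns 'label' and 'name'")
    return {int(r.label): str(r.name) for r in df.itertuples()}


def write_label_atlas(path, names_path, atlas: LabelAtlas) -> None:
    _save(path, atlas.labels.astype(np.int32), atlas.grid, dtype=np.int32)
    rows = sorted(atlas.names.items())
    pd.DataFrame(rows, columns=["label", "name"]).to_csv(names_path, index=False)


def read_cohort_table(path) -> pd.DataFrame:
    """Read the cohort CSV: one row per (subject, interval).

    Required columns: subject_id, interval_id, days_between_scans,
    midpoint_age_days.  Any extra columns (e.g. map paths) pass through.
    """
    df = pd.read_csv(path)
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if (df["days_between_scans"] <= 0).any():
        raise ValueError("days_between_scans must be positive")
    if (df["midpoint_age_days"] <= 0).any():
        raise ValueError("midpoint_age_days must be positive")
    dup = df.duplicated(subset=["subject_id", "interval_id"])
    if dup.any():
        raise ValueError(
            f"cohort table has {int(dup.sum())} duplicate (subject, interval) row(s)"
        )
    return df


def write_table(path, df: pd.DataFrame) -> None:
    """Write a results table as CSV with a header row."""
    df.to_csv(path, index=False)
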