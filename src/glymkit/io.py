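"""NIfTI / gradient-table / cohort-table readers and writers, plus resampling.

All image traffic is NIfTI-1/2 via nibabel.  Gradient tables use the FSL
two-file dialect (``.bval`` one row of b-values; ``.bvec`` three rows of
direction components).  Cohort tables are CSV with a fixed, versioned header.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import LabelMap, Volume

logger = logging.getLogger("glymkit")

__all__ = [
    "GradientTable",
    "read_volume",
    "write_volume",
    "read_gradient_table",
    "resample_volume",
    "resample_labels",
    "read_cohort_table",
    "write_cohort_table",
    "VISIT_LABELS",
    "COHORT_SCHEMA_VERSION",
]


@dataclass(frozen=True)
class GradientTable:
    """Diffusion encoding: per-volume b-value (s/mm^2) and unit direction."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvals ({bvals.size}) and bvecs ({bvecs.shape}) lengths differ"
            )
        if not np.any(bvals == 0):
            raise ValueError("gradient table needs at least one b=0 entry")
        nz = bvals > 0
        norms = np.linalg.norm(bvecs[nz], axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero direction vector with b > 0")
        if np.any(np.abs(norms - 1.0) > 1e-3):
            logger.warning(
                "renormalizing %d non-unit diffusion directions",
                int(np.sum(np.abs(norms - 1.0) > 1e-3)),
            )
        bvecs = bvecs.copy()
        bvecs[nz] = bvecs[nz] / norms[:, None]
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return int(self.bvals.size)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def shells(self) -> np.ndarray:
        return np.unique(self.bvals[self.bvals > 0])


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a 3-D NIfTI image into a :class:`Volume`.

    Rejects 4-D payloads and non-finite voxels outright: every stage of the
    pipeline assumes clean scalar 3-D input.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D payload, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data.astype(np.float64), spacing=spacing, affine=np.asarray(img.affine))


def write_volume(v: Volume, path: str | os.PathLike, overwrite: bool = True) -> str:
    """Write a :class:`Volume` as float64 NIfTI (lossless round trip)."""
    path = str(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists and overwrite=False")
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float64), np.asarray(v.affine))
    img.header.set_zooms(v.spacing)
    nib.save(img, path)
    return path


def read_dwi_series(path: str | os.PathLike) -> tuple[np.ndarray, tuple, np.ndarray]:
    """Read a 4-D diffusion series; returns (data, spacing, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4-D DWI, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def write_dwi_series(
    data: np.ndarray, spacing: tuple, affine: np.ndarray, path: str | os.PathLike
) -> str:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine))
    img.header.set_zooms(tuple(spacing) + (1.0,))
    nib.save(img, str(path))
    return str(path)


def read_gradient_table(bval_path: str | os.PathLike, bvec_path: str | os.PathLike) -> GradientTable:
    """Parse FSL-dialect ``.bval``/``.bvec`` files.

    Non-unit nonzero directions are renormalized (with a logged warning,
    handled by :class:`GradientTable`); a length mismatch between the two
    files is an error.
    """
    bvals = np.loadtxt(str(bval_path), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3; FSL convention is 3 rows x N columns
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"bval ({bvals.size}) and bvec ({bvecs.shape[0]}) entry counts differ"
        )
    return GradientTable(bvals=bvals, bvecs=bvecs)


def write_gradient_table(
    gtab: GradientTable, bval_path: str | os.PathLike, bvec_path: str | os.PathLike
) -> None:
    np.savetxt(str(bval_path), gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), gtab.bvecs.T, fmt="%.8f")


def resample_volume(
    v: Volume, target_spacing: tuple[float, float, float], mode: str = "linear"
) -> Volume:
    """Resample onto an isotropic-or-not grid covering the same world extent.

    ``linear`` uses order-1 interpolation (never overshoots the input range);
    ``nearest`` is for label payloads.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be linear|nearest, got {mode!r}")
    order = 1 if mode == "linear" else 0
    zoom = [vs / ts for vs, ts in zip(v.spacing, target_spacing)]
    new_shape = tuple(max(1, int(round(n * z))) for n, z in zip(v.shape, zoom))
    # sample the old grid at the new voxel centers (world-extent preserving)
    coords = np.meshgrid(
        *[
            (np.arange(ns) + 0.5) * ts / vs - 0.5
            for ns, ts, vs in zip(new_shape, target_spacing, v.spacing)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        np.asarray(v.data, dtype=float), np.stack(coords), order=order, mode="nearest"
    )
    scale = np.diag(list(target_spacing) + [1.0]) @ np.linalg.inv(
        np.diag(list(v.spacing) + [1.0])
    )
    new_affine = np.asarray(v.affine) @ scale
    return Volume(data=out, spacing=target_spacing, affine=new_affine, space_tag=v.space_tag)


def resample_labels(lm: LabelMap, target_spacing: tuple[float, float, float]) -> LabelMap:
    """Nearest-neighbour resampling of a label map (introduces no new labels)."""
    v = Volume(data=lm.labels.astype(float), spacing=lm.spacing, affine=lm.affine)
    out = resample_volume(v, target_spacing, mode="nearest")
    return LabelMap(
        labels=out.data.astype(lm.labels.dtype),
        legend=dict(lm.legend),
        spacing=out.spacing,
        affine=out.affine,
    )


# ---------------------------------------------------------------------------
# Cohort table

COHORT_SCHEMA_VERSION = "glymkit-cohort-v1"
VISIT_LABELS = ("14Day", "6-12Mon", "control")

N_RPQ_ITEMS = 22
RPQ_COLUMNS = [f"rpq_item_{i:02d}" for i in range(1, N_RPQ_ITEMS + 1)]
# item 4 of the modified Rivermead questionnaire probes forgetfulness /
# poor memory; the memory-problem flag derives from it.
MEMORY_ITEM_INDEX = 3

BASE_COLUMNS = [
    "subject_id",
    "group",
    "visit",
    "age",
    "sex",
    "education",
    "gcs",
    "ct_or_mri_positive",
    "rpq_total",
    "n_symptoms",
    "memory_problem",
    "psqi",
    "wm_epvs",
    "bg_epvs",
    "alps_index",
]
COHORT_COLUMNS = BASE_COLUMNS + RPQ_COLUMNS


def _validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad_visit = set(df["visit"].unique()) - set(VISIT_LABELS)
    if bad_visit:
        raise ValueError(f"unknown visit labels: {sorted(bad_visit)}")
    dup = df.duplicated(subset=["subject_id", "visit"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject_id, visit) pairs: "
            f"{df.loc[dup, ['subject_id', 'visit']].values.tolist()}"
        )
    age = pd.to_numeric(df["age"], errors="coerce")
    if age.isna().any():
        raise ValueError("non-numeric age values present")
    df = df.copy()
    df["age"] = age.astype(float)
    items = df[RPQ_COLUMNS].to_numpy(dtype=float)
    finite = np.isfinite(items)
    if np.any((items[finite] < 0) | (items[finite] > 4)):
        raise ValueError("RPQ item ratings must lie in 0..4 (5-point ordinal scale)")
    return df


def read_cohort_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a cohort CSV (typed columns, unique subject-visit)."""
    df = pd.read_csv(str(path), comment="#")
    return _validate_cohort(df)


def write_cohort_table(df: pd.DataFrame, path: str | os.PathLike) -> str:
    _validate_cohort(df)
    path = str(path)
    with open(path, "w") as fh:
        fh.write(f"# {COHORT_SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)
    return path
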