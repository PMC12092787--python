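"""NIfTI volume I/O, preprocessing, and measure-matrix construction.

Grey-matter images enter the pipeline as per-subject 3D volumes sharing one
grid and one affine (RAS+ world convention, millimetres).  They are
optionally resampled and smoothed, reduced to a brain mask, and vectorized
into the subjects x in-mask-voxels *measure matrix* on which the ICA
decomposition operates.

Voxel enumeration
-----------------
Everywhere a flat voxel index appears, voxels are enumerated in ascending
flat index with x varying fastest (Fortran order on an (nx, ny, nz) grid).
This order is fixed, deterministic, and shared by masks, measure-matrix
columns and cluster voxel lists.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import (
    MaskError,
    MetadataError,
    ShapeMismatchError,
    ValidationError,
)

#: conversion factor between a Gaussian FWHM and its standard deviation
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: required participants-table columns, in canonical order
REQUIRED_COLUMNS = ("participant_id", "group", "age", "tiv")

#: clinical score columns produced by the synthetic generator and consumed
#: by the correlation module; real tables may carry any subset
CLINICAL_COLUMNS = (
    "PCS",
    "helplessness",
    "magnification",
    "rumination",
    "PSP",
    "STAI",
    "CESD",
    "pain_intensity",
    "fm_years",
)

GROUP_LABELS = ("patient", "control")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VolumeSet:
    """A stack of per-subject 3D scalar volumes on a common grid.

    Parameters
    ----------
    subject_ids
        Ordered subject identifiers, one per volume.
    data
        Array of shape ``(n_subjects, nx, ny, nz)``, nonnegative grey-matter
        volume/probability values.
    affine
        4x4 voxel-to-world transform shared by all subjects (mm, RAS+).
    """

    subject_ids: list[str]
    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ShapeMismatchError(
                f"data must be (n_subjects, nx, ny, nz), got shape {self.data.shape}"
            )
        if len(self.subject_ids) != self.data.shape[0]:
            raise MetadataError(
                f"{len(self.subject_ids)} subject ids for {self.data.shape[0]} volumes"
            )
        if self.data.shape[0] < 2:
            raise ValidationError("at least 2 subjects required")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if not np.isfinite(self.data).all():
            raise ValidationError("volume data contain NaN/Inf values")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, per axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class BrainMask:
    """Boolean analysis mask on a volume grid with a fixed voxel enumeration."""

    grid: np.ndarray
    linear_index: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise MaskError("mask grid must be 3D")
        # ascending flat index, x fastest (Fortran order)
        self.linear_index = np.flatnonzero(self.grid.ravel(order="F"))
        if self.n_voxels < 1:
            raise MaskError("mask contains no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class MeasureMatrix:
    """Subjects x in-mask-voxels data matrix, one vectorized image per row."""

    values: np.ndarray
    mask: BrainMask
    subject_ids: list[str]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeMismatchError("measure matrix must be 2D")
        if self.values.shape[0] != len(self.subject_ids):
            raise MetadataError("row count does not match number of subjects")
        if self.values.shape[1] != self.mask.n_voxels:
            raise ShapeMismatchError(
                f"{self.values.shape[1]} columns for a mask of "
                f"{self.mask.n_voxels} voxels"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("measure matrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# participants table
# ---------------------------------------------------------------------------


def read_participants(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BIDS-flavoured ``participants.tsv`` (tab-separated, ``n/a`` missing)."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"], dtype={"participant_id": str})
    validate_participants(df)
    return df


def write_participants(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")


def validate_participants(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"participants table missing columns: {missing}")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise MetadataError(f"duplicate participant ids: {dup}")
    bad = set(df["group"]) - set(GROUP_LABELS)
    if bad:
        raise MetadataError(
            f"unknown group labels {sorted(bad)}; expected {GROUP_LABELS}"
        )
    if df["group"].nunique() < 2:
        raise MetadataError("both groups (patient, control) must be represented")


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------


def load_volumes(
    paths: list[str | os.PathLike], participants: str | os.PathLike | pd.DataFrame
) -> tuple[VolumeSet, pd.DataFrame]:
    """Load per-subject NIfTI volumes together with their participants table.

    Each file name must contain exactly one ``participant_id`` from the
    table.  Subject order in the returned :class:`VolumeSet` follows the
    table, not the path list.
    """
    if isinstance(participants, pd.DataFrame):
        table = participants.copy()
        validate_participants(table)
    else:
        table = read_participants(participants)
    if len(paths) < 2:
        raise ValidationError("at least 2 subjects required")

    ids = list(table["participant_id"])
    by_subject: dict[str, Path] = {}
    for p in paths:
        p = Path(p)
        stem = p.name
        hits = [s for s in ids if s in stem]
        if not hits:
            raise MetadataError(f"file {p.name} matches no participant_id in table")
        # prefer the longest match to disambiguate e.g. sub-1 vs sub-11
        sid = max(hits, key=len)
        if sid in by_subject:
            raise MetadataError(f"participant {sid} matched by multiple files")
        by_subject[sid] = p

    present = [s for s in ids if s in by_subject]
    if len(present) != len(by_subject):  # pragma: no cover - guarded above
        raise MetadataError("file/participant matching is inconsistent")
    table = table[table["participant_id"].isin(present)].reset_index(drop=True)
    validate_participants(table)

    arrays, affine, shape = [], None, None
    for sid in table["participant_id"]:
        img = nib.load(str(by_subject[sid]))
        arr = np.asarray(img.get_fdata(), dtype=float)
        if shape is None:
            shape, affine = arr.shape, img.affine
        else:
            if arr.shape != shape:
                raise ShapeMismatchError(
                    f"{by_subject[sid].name}: grid {arr.shape} != expected {shape}"
                )
            if not np.allclose(img.affine, affine, atol=1e-4):
                raise ShapeMismatchError(
                    f"{by_subject[sid].name}: affine differs from the first volume"
                )
        arrays.append(arr)

    vs = VolumeSet(list(table["participant_id"]), np.stack(arrays), affine)
    return vs, table


def write_volumes(vs: VolumeSet, out_dir: str | os.PathLike, suffix: str = ".nii.gz") -> list[Path]:
    """Write one NIfTI file per subject; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid, arr in zip(vs.subject_ids, vs.data):
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), vs.affine)
        p = out_dir / f"{sid}{suffix}"
        nib.save(img, str(p))
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def resample_volume(
    vs: VolumeSet, target_voxel_mm: float | tuple[float, float, float], order: int = 1
) -> VolumeSet:
    """Resample every subject onto a grid with the requested voxel size.

    Trilinear interpolation (``order=1``) by default; use ``order=0``
    (nearest neighbour) for label volumes.  The new grid covers the same
    world bounding box, keeping the corner voxel's world position fixed.
    """
    target = np.broadcast_to(np.asarray(target_voxel_mm, dtype=float), (3,)).copy()
    if np.any(target <= 0):
        raise ValidationError(f"target voxel size must be positive, got {target}")
    old = vs.voxel_size
    zoom = target / old
    if np.allclose(zoom, 1.0, atol=1e-12):
        return VolumeSet(list(vs.subject_ids), vs.data.copy(), vs.affine.copy())
    new_shape = tuple(int(np.ceil(s / z)) for s, z in zip(vs.grid_shape, zoom))
    matrix = np.diag(zoom)
    out = np.empty((vs.n_subjects, *new_shape), dtype=float)
    for i in range(vs.n_subjects):
        ndimage.affine_transform(
            vs.data[i],
            matrix=matrix,
            output_shape=new_shape,
            output=out[i],
            order=order,
            mode="constant",
            cval=0.0,
        )
    new_affine = vs.affine.copy()
    new_affine[:3, :3] = vs.affine[:3, :3] @ matrix
    return VolumeSet(list(vs.subject_ids), out, new_affine)


def smooth_volumes(vs: VolumeSet, fwhm_mm: float, truncate: float = 4.0) -> VolumeSet:
    """Gaussian-smooth each subject's volume with an isotropic mm-space kernel.

    ``sigma_mm = fwhm_mm / (2 sqrt(2 ln 2))`` is converted to voxel units per
    axis; boundaries are zero-padded (volumes are zero outside the head).
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValidationError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return VolumeSet(list(vs.subject_ids), vs.data.copy(), vs.affine.copy())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vs.voxel_size
    out = np.empty_like(vs.data)
    for i in range(vs.n_subjects):
        ndimage.gaussian_filter(
            vs.data[i], sigma=sigma_vox, output=out[i], mode="constant",
            cval=0.0, truncate=truncate,
        )
    return VolumeSet(list(vs.subject_ids), out, vs.affine.copy())


def build_mask(
    vs: VolumeSet, mean_threshold: float = 0.1, require_variance: bool = True
) -> BrainMask:
    """Liberal grey-matter analysis mask.

    A voxel is included iff its across-subject mean exceeds
    ``mean_threshold`` and, when ``require_variance`` is set, its
    across-subject variance is strictly positive (constant voxels carry no
    between-subject signal and break standardization).
    """
    if mean_threshold < 0:
        raise ValidationError("mean_threshold must be >= 0")
    mean = vs.data.mean(axis=0)
    keep = mean > mean_threshold
    if require_variance:
        keep &= vs.data.var(axis=0) > 0
    if not keep.any():
        raise MaskError(f"mask empty at threshold {mean_threshold}")
    return BrainMask(keep)


# ---------------------------------------------------------------------------
# vectorization
# ---------------------------------------------------------------------------


def _flatten(volume: np.ndarray) -> np.ndarray:
    return volume.ravel(order="F")


def vectorize(vs: VolumeSet, mask: BrainMask) -> MeasureMatrix:
    """Extract in-mask voxels into the measure matrix (one row per subject)."""
    if mask.grid.shape != vs.grid_shape:
        raise ShapeMismatchError(
            f"mask grid {mask.grid.shape} does not match volume grid {vs.grid_shape}"
        )
    flat = np.stack([_flatten(vol) for vol in vs.data])
    values = flat[:, mask.linear_index]
    return MeasureMatrix(values, mask, list(vs.subject_ids), vs.affine.copy())


def map_to_volume(values: np.ndarray, mask: BrainMask) -> np.ndarray:
    """Inverse of :func:`vectorize`: scatter rows back onto the 3D grid.

    ``values`` may be a single ``(n_voxels,)`` vector (returns 3D) or a
    ``(k, n_voxels)`` matrix (returns ``(k, nx, ny, nz)``).  Out-of-mask
    voxels are zero.
    """
    values = np.asarray(values, dtype=float)
    single = values.ndim == 1
    rows = values[None, :] if single else values
    if rows.shape[1] != mask.n_voxels:
        raise ShapeMismatchError(
            f"{rows.shape[1]} values for a mask of {mask.n_voxels} voxels"
        )
    out = np.zeros((rows.shape[0], int(np.prod(mask.grid.shape))))
    out[:, mask.linear_index] = rows
    vols = out.reshape((rows.shape[0], *mask.grid.shape), order="F")
    return vols[0] if single else vols


# ---------------------------------------------------------------------------
# component map I/O
# ---------------------------------------------------------------------------


def write_component_maps(
    maps: np.ndarray,
    mask: BrainMask,
    affine: np.ndarray,
    path: str | os.PathLike,
) -> Path:
    """Write per-component Z maps as one 4D NIfTI (x, y, z, component).

    ``maps`` is either ``(k, n_voxels)`` (in-mask rows) or ``(k, nx, ny, nz)``.
    Values are stored as float32; out-of-mask voxels are zero.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.size == 0 or maps.shape[0] == 0:
        raise ValidationError("nothing to write: zero components")
    if maps.ndim == 2:
        vols = map_to_volume(maps, mask)
    elif maps.ndim == 4:
        if maps.shape[1:] != mask.grid.shape:
            raise ShapeMismatchError("component grids do not match the mask grid")
        vols = maps * mask.grid[None]
    else:
        raise ShapeMismatchError("maps must be (k, n_voxels) or (k, nx, ny, nz)")
    data4d = np.moveaxis(vols, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(data4d, np.asarray(affine, dtype=float))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_component_maps(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read a 4D component-map NIfTI; returns ``(k, nx, ny, nz)`` and the affine."""
    img = nib.load(str(path))
    arr = np.asarray(img.get_fdata(), dtype=float)
    if arr.ndim != 4:
        raise ShapeMismatchError(f"expected 4D component maps, got {arr.ndim}D")
    return np.moveaxis(arr, -1, 0), img.affine


def write_mask(mask: BrainMask, affine: np.ndarray, path: str | os.PathLike) -> Path:
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), np.asarray(affine, dtype=float))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_mask(path: str | os.PathLike) -> tuple[BrainMask, np.ndarray]:
    img = nib.load(str(path))
    grid = np.asarray(img.get_fdata()) > 0.5
    return BrainMask(grid), img.affine
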