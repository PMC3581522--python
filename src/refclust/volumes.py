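"""Volume and mask containers, NIfTI I/O, grid checks, and the cohort manifest.

All analysis happens in voxel space on a common grid: images are assumed to be
spatially normalized already, so the affine is carried opaquely from input to
output and never used for resampling.  Out-of-brain voxels are NaN and every
reduction in the package ignores them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


class RefclustError(Exception):
    """Base class for errors raised by this package."""


class GridError(RefclustError):
    """A volume is not a 3D grid or cannot be read as one."""


class GridMismatchError(RefclustError):
    """Two volumes do not live on the same grid."""


class ManifestError(RefclustError):
    """The cohort manifest is malformed."""


def _default_affine(voxel_size: float = 2.0) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


@dataclass
class VolumeImage:
    """One subject's 3D scalar uptake grid plus opaque geometry (affine)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise GridError(f"not a 3D volume: shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths in mm, read off the affine columns."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        return VolumeImage(np.asarray(data, dtype=float), self.affine.copy())


@dataclass
class MaskVolume:
    """Binary mask on the same grid as its companion volumes."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        vals = np.unique(arr[np.isfinite(arr)]) if arr.dtype.kind == "f" else np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise GridError("mask values must be 0/1")
        self.data = arr.astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise GridError(f"not a 3D mask: shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelVolume:
    """Integer parcellation; label 0 is background, others named in label_table."""

    data: np.ndarray
    label_table: dict[int, str]
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(int)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise GridError(f"not a 3D label volume: shape {self.data.shape}")
        if (self.data < 0).any():
            raise GridError("labels must be non-negative")
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise GridError(f"labels {sorted(missing)} absent from label_table")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def id_of(self, name: str) -> int:
        for k, v in self.label_table.items():
            if v == name:
                return k
        raise KeyError(name)


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI volume; a 4D file with a singleton last axis is accepted as 3D."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        affine = np.asarray(img.affine, dtype=float)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt/unreadable header
        raise GridError(f"unreadable volume {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GridError(f"{path}: not a 3D volume (shape {data.shape})")
    return VolumeImage(data, affine)


def write_volume(img: VolumeImage | MaskVolume, path: str | Path) -> None:
    """Write as NIfTI-1; masks are stored as uint8 {0,1}, images as float64."""
    path = Path(path)
    if isinstance(img, MaskVolume):
        out = nib.Nifti1Image(img.data.astype(np.uint8), img.affine)
    else:
        out = nib.Nifti1Image(img.data.astype(np.float64), img.affine)
    nib.save(out, str(path))


def read_mask(path: str | Path) -> MaskVolume:
    vol = read_volume(path)
    return MaskVolume(vol.data > 0.5, vol.affine)


def assert_same_grid(a, b, tol_mm: float = 1e-5) -> None:
    """Check shape equality and voxel size agreement to tol_mm; no resampling ever."""
    if tuple(a.shape) != tuple(b.shape):
        raise GridMismatchError(f"grid shapes differ: {tuple(a.shape)} vs {tuple(b.shape)}")
    va, vb = np.asarray(a.voxel_size), np.asarray(b.voxel_size)
    if np.any(np.abs(va - vb) > tol_mm):
        raise GridMismatchError(f"voxel sizes differ: {va} vs {vb} mm")


def mask_from_labels(labels: LabelVolume, wanted: set[int] | list[int]) -> MaskVolume:
    """Union of the listed parcels as a binary mask (e.g. cerebellar VOI from atlas ids)."""
    wanted = set(int(w) for w in wanted)
    if not wanted:
        raise ValueError("wanted label set is empty")
    unknown = wanted - set(labels.label_table)
    if unknown:
        raise KeyError(f"unknown label ids: {sorted(unknown)}")
    mask = np.isin(labels.data, sorted(wanted))
    return MaskVolume(mask, labels.affine)


def dice(a: MaskVolume | np.ndarray, b: MaskVolume | np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) between two binary masks (1.0 if both empty)."""
    da = a.data if isinstance(a, MaskVolume) else np.asarray(a, bool)
    db = b.data if isinstance(b, MaskVolume) else np.asarray(b, bool)
    if da.shape != db.shape:
        raise GridMismatchError(f"grid shapes differ: {da.shape} vs {db.shape}")
    denom = da.sum() + db.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (da & db).sum() / denom)


MANIFEST_COLUMNS = ("id", "group", "age", "sex", "path")
GROUPS = ("control", "patient")


@dataclass
class CohortManifest:
    """Subjects of one cohort: id, group (control/patient), age (years), sex (0/1), path."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ManifestError(f"manifest missing columns: {sorted(missing)}")
        df = df.loc[:, list(MANIFEST_COLUMNS)].reset_index(drop=True)
        if df["id"].duplicated().any():
            raise ManifestError("subject ids are not unique")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise ManifestError(f"group must be 'control'/'patient', got {sorted(bad)}")
        for g in GROUPS:
            if not (df["group"] == g).any():
                raise ManifestError(f"no subjects in group '{g}'")
        if not np.all(np.isfinite(df["age"].astype(float))):
            raise ManifestError("non-finite ages")
        if not df["sex"].astype(int).isin((0, 1)).all():
            raise ManifestError("sex must be coded 0/1")
        df["age"] = df["age"].astype(float)
        df["sex"] = df["sex"].astype(int)
        self.table = df

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortManifest":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def group_indicator(self) -> np.ndarray:
        """1 for patients, 0 for controls, in manifest order."""
        return (self.table["group"] == "patient").to_numpy().astype(int)

    @property
    def n_controls(self) -> int:
        return int((self.table["group"] == "control").sum())

    @property
    def n_patients(self) -> int:
        return int((self.table["group"] == "patient").sum())
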