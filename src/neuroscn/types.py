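"""Core data containers.

The pipeline works on already-segmented, spatially registered gray-matter
volumes.  Three containers travel between modules: :class:`GMVolume` (one
subject's scalar gray-matter image), :class:`Parcellation` (an integer-labeled
region atlas sharing the volume grid), and a validated phenotype table
(pandas ``DataFrame``).  All world coordinates are derived from the NIfTI
affine through :func:`voxel_to_world`, the single shared utility, so peak
reports and sphere extraction agree voxel-for-voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Regions with fewer voxels than this are rejected at load: a kernel density
#: estimate over fewer values is not meaningful.
MIN_ROI_VOXELS = 10

GROUP_LEVELS = ("patient", "control")
SEX_LEVELS = ("M", "F")

PHENOTYPE_COLUMNS = ("subject_id", "group", "age", "sex", "tiv", "hamd17")


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map 0-based voxel indices to world (mm) coordinates via a 4x4 affine.

    Parameters
    ----------
    affine : (4, 4) array
    ijk : (..., 3) array of voxel indices (may be fractional).

    Returns
    -------
    (..., 3) array of world coordinates in mm.
    """
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voxel_to_world` (fractional voxel indices)."""
    xyz = np.asarray(xyz, dtype=float)
    inv = np.linalg.inv(affine)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class GMVolume:
    """A single subject's registered gray-matter image.

    Attributes
    ----------
    subject_id : str
    data : (X, Y, Z) float array, non-negative and finite.
    affine : (4, 4) voxel-to-world transform in mm.
    """

    subject_id: str
    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got {self.data.ndim}D for {self.subject_id!r}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValueError(
                f"volume {self.subject_id!r} contains {n_bad} non-finite voxels"
            )
        if np.any(self.data < 0):
            raise ValueError(f"volume {self.subject_id!r} contains negative voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge length in mm, from the affine columns."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        return voxel_to_world(self.affine, ijk)


@dataclass
class Parcellation:
    """Integer-labeled region atlas: 0 = background, 1..R = region ids."""

    labels: np.ndarray
    roi_names: dict[int, str]
    affine: np.ndarray
    min_roi_voxels: int = MIN_ROI_VOXELS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("parcellation labels must be integer-valued")
            self.labels = as_int
        if self.labels.ndim != 3:
            raise ValueError("parcellation must be a 3D label grid")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        ids = np.unique(self.labels)
        ids = ids[ids > 0]
        expected = np.arange(1, len(self.roi_names) + 1)
        if not np.array_equal(ids, expected):
            raise ValueError(
                "region ids must be contiguous 1..R and match the lookup table; "
                f"image has {ids.tolist()[:10]}..., table has {len(self.roi_names)} rows"
            )
        counts = np.bincount(self.labels.ravel())[1:]
        small = np.flatnonzero(counts < self.min_roi_voxels) + 1
        if small.size:
            raise ValueError(
                f"regions smaller than {self.min_roi_voxels} voxels: {small.tolist()}"
            )

    @property
    def n_roi(self) -> int:
        return len(self.roi_names)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def roi_mask(self, roi_id: int) -> np.ndarray:
        if not 1 <= roi_id <= self.n_roi:
            raise ValueError(f"roi_id {roi_id} outside 1..{self.n_roi}")
        return self.labels == roi_id


def check_same_grid(vol: GMVolume, parc: Parcellation) -> None:
    """Volumes and parcellation must live on an identical grid — never resample."""
    if vol.shape != parc.shape:
        raise ValueError(
            f"volume grid {vol.shape} does not match parcellation grid {parc.shape}; "
            "resample upstream explicitly"
        )
    if not np.allclose(vol.affine, parc.affine, atol=1e-4):
        raise ValueError("volume and parcellation affines differ")


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a phenotype table.

    Required columns: subject_id, group (patient/control), age, sex (M/F),
    tiv.  hamd17 is optional per subject (typically missing for controls)
    but the column must exist.
    """
    df = df.copy()
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns and c != "hamd17"]
    if missing:
        raise ValueError(f"phenotype table missing required columns: {missing}")
    if "hamd17" not in df.columns:
        df["hamd17"] = np.nan
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicated subject_id values: {dup}")
    bad_group = set(df["group"].unique()) - set(GROUP_LEVELS)
    if bad_group:
        raise ValueError(f"unknown group levels {sorted(bad_group)}; expected {GROUP_LEVELS}")
    bad_sex = set(df["sex"].unique()) - set(SEX_LEVELS)
    if bad_sex:
        raise ValueError(f"unknown sex levels {sorted(bad_sex)}; expected {SEX_LEVELS}")
    for col in ("age", "tiv"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if df[col].isna().any():
            raise ValueError(f"missing values in required column {col!r}")
    df["hamd17"] = pd.to_numeric(df["hamd17"], errors="coerce")
    present = df["hamd17"].dropna()
    if (present < 0).any():
        raise ValueError("hamd17 scores must be non-negative")
    df["subject_id"] = df["subject_id"].astype(str)
    return df.reset_index(drop=True)


#: Column order of the cluster report table.
CLUSTER_TABLE_COLUMNS = (
    "tail",
    "cluster_id",
    "cluster_size_voxels",
    "peak_t",
    "peak_x_mm",
    "peak_y_mm",
    "peak_z_mm",
    "cluster_p",
)


def empty_cluster_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        CLUSTER_TABLE_COLUMNS,
        (str, int, int, float, float, float, float, float),
    )})
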