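"""Readers and writers: NIfTI volumes/parcellations, TSV tables.

Conventions
-----------
* Images are canonicalized to RAS axis order on load (once, here); a grid
  mismatch downstream is an error, never an automatic resample.
* Every tabular artifact is TSV: tab-separated, UTF-8, '.' decimal, floats
  at 6 significant digits.  This single dialect round-trips bit-exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    CLUSTER_TABLE_COLUMNS,
    GMVolume,
    Parcellation,
    empty_cluster_table,
    validate_phenotypes,
)

FLOAT_FMT = "%.6g"


def _load_canonical(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    return nib.as_closest_canonical(img)


def read_volume(path: str | Path, subject_id: str | None = None) -> GMVolume:
    """Read one 3D gray-matter NIfTI volume (RAS-canonicalized).

    Raises on 4D input and on non-finite voxels (reporting the count);
    orientation is normalized exactly once, here.
    """
    img = _load_canonical(path)
    data = np.asarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D: {path}")
    n_bad = int(data.size - np.isfinite(data).sum())
    if n_bad:
        raise ValueError(f"{path}: {n_bad} non-finite (NaN/inf) voxels")
    if subject_id is None:
        name = Path(path).name
        for suffix in (".nii.gz", ".nii"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
                break
        subject_id = name
    return GMVolume(subject_id=subject_id, data=data.astype(np.float64),
                    affine=np.asarray(img.affine))


def write_volume(vol: GMVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1, float32 data, affine preserved exactly."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def write_image(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write an arbitrary 3D scalar image (e.g. a signed t-map) as NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_parcellation(path: str | Path, lut_path: str | Path) -> Parcellation:
    """Read an integer label image plus its id/name lookup table (TSV).

    Region ids must be contiguous 1..R; any id present in the image but
    absent from the table (or vice versa) is an error.
    """
    img = _load_canonical(path)
    labels = np.asarray(img.dataobj)
    if labels.ndim != 3:
        raise ValueError(f"expected 3D label image, got {labels.ndim}D")
    as_int = np.round(labels).astype(np.int64)
    if not np.allclose(labels, as_int, atol=1e-6):
        raise ValueError("parcellation image is not integer-valued")
    lut = pd.read_csv(lut_path, sep="\t")
    if not {"id", "name"} <= set(lut.columns):
        raise ValueError("lookup table must have columns 'id' and 'name'")
    if lut["id"].duplicated().any():
        raise ValueError("duplicate ids in lookup table")
    roi_names = {int(r.id): str(r.name) for r in lut.itertuples()}
    image_ids = set(np.unique(as_int).tolist()) - {0}
    missing = sorted(image_ids - set(roi_names))
    if missing:
        raise ValueError(f"image region ids missing from lookup table: {missing}")
    return Parcellation(labels=as_int, roi_names=roi_names,
                        affine=np.asarray(img.affine))


def write_parcellation(parc: Parcellation, path: str | Path,
                       lut_path: str | Path) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int16), parc.affine)
    nib.save(img, str(path))
    lut = pd.DataFrame(
        {"id": list(parc.roi_names), "name": list(parc.roi_names.values())}
    )
    lut.to_csv(lut_path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate the phenotype TSV (subject_id, group, age, sex, tiv, hamd17)."""
    df = pd.read_csv(path, sep="\t")
    return validate_phenotypes(df)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_cluster_table(clusters: pd.DataFrame, path: str | Path) -> None:
    """Write a cluster report TSV (header always present, even when empty)."""
    if clusters is None or len(clusters) == 0:
        clusters = empty_cluster_table()
    clusters = clusters[list(CLUSTER_TABLE_COLUMNS)]
    clusters.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(matrix: np.ndarray, roi_names: dict[int, str] | list[str],
                 path: str | Path) -> None:
    """Write an ROI-by-ROI matrix as TSV with region names as header and index."""
    if isinstance(roi_names, dict):
        names = [roi_names[i] for i in sorted(roi_names)]
    else:
        names = list(roi_names)
    matrix = np.asarray(matrix)
    if matrix.shape != (len(names), len(names)):
        raise ValueError(f"matrix shape {matrix.shape} != ({len(names)}, {len(names)})")
    df = pd.DataFrame(matrix, index=names, columns=names)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="roi")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


def write_edge_table(edges: pd.DataFrame, path: str | Path) -> None:
    """Write a per-edge report TSV (node names, edge t, component FWER p)."""
    edges.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def ensure_dir(path: str | Path) -> Path:
    path = Path(path)
    os.makedirs(path, exist_ok=True)
    return path
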