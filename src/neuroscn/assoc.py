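"""Post-hoc clinical associations and demographic tests.

Signal extraction from significant clusters (or 8 mm spheres around their
peaks, for the sensitivity analysis), covariate-adjusted Pearson
correlations with the symptom score, Benjamini-Hochberg FDR over result
families, and the two demographic tests (Pearson chi-square without
continuity correction; two-sample t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GMVolume, world_to_voxel


@dataclass
class AssociationResult:
    """A covariate-adjusted Pearson correlation between a measure and a score."""

    measure_id: str
    r: float
    p: float
    n: int
    covariates: tuple[str, ...]
    q: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"correlation out of range: {self.r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value out of range: {self.p}")


def extract_cluster_mean(vol: GMVolume, cluster_mask: np.ndarray) -> float:
    """Mean gray-matter value over a cluster's voxels."""
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if cluster_mask.shape != vol.shape:
        raise ValueError("cluster mask grid does not match volume")
    if not cluster_mask.any():
        raise ValueError("empty cluster mask")
    return float(vol.data[cluster_mask].mean())


def extract_sphere_mean(vol: GMVolume, center_mm, radius_mm: float) -> float:
    """Mean over voxels whose world-coordinate centers lie within the sphere."""
    center_mm = np.asarray(center_mm, dtype=float)
    center_vox = world_to_voxel(vol.affine, center_mm)
    vox = vol.voxel_size_mm
    half = np.ceil(radius_mm / vox).astype(int) + 1
    lo = np.maximum(np.floor(center_vox).astype(int) - half, 0)
    hi = np.minimum(np.floor(center_vox).astype(int) + half + 1, vol.shape)
    if np.any(lo >= hi):
        raise ValueError("sphere does not intersect the image grid")
    ii, jj, kk = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                             indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = vol.world_coords(ijk)
    inside = np.linalg.norm(world - center_mm, axis=1) <= radius_mm
    if not inside.any():
        raise ValueError("no voxel center within the sphere radius")
    sel = ijk[inside]
    return float(vol.data[sel[:, 0], sel[:, 1], sel[:, 2]].mean())


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ coef


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    measure_id: str = "",
    covariate_names: tuple[str, ...] = (),
) -> AssociationResult:
    """Pearson correlation of x and y after regressing out covariates.

    Both variables are residualized on [1, covariates]; the p-value uses the
    t transform with df = n - 2 - k covariates.  With no covariates this is
    the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in x or y")
    n = len(x)
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        Z = np.column_stack([np.ones(n), covariates])
        k = Z.shape[1] - 1
    if n <= k + 2:
        raise ValueError(f"need more than {k + 2} observations, got {n}")
    rx, ry = _residualize(x, Z), _residualize(y, Z)
    sx, sy = rx.std(), ry.std()
    if sx <= 1e-12 * max(1.0, np.abs(x).max()) or \
            sy <= 1e-12 * max(1.0, np.abs(y).max()):
        raise ValueError("zero residual variance")
    r = float(np.clip((rx @ ry) / (n * sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        tval = r * np.sqrt(df / (1 - r ** 2))
        p = float(2 * stats.t.sf(abs(tval), df))
    return AssociationResult(measure_id=measure_id, r=r, p=p, n=n,
                             covariates=covariate_names)


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return q.reshape(p.shape)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction, df=1."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def two_sample_t(a, b, variant: str = "pooled") -> tuple[float, float]:
    """Two-sample t-test, pooled-variance (Student) or Welch, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    if variant == "pooled":
        res = stats.ttest_ind(a, b, equal_var=True)
    elif variant == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(res.statistic), float(res.pvalue)
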