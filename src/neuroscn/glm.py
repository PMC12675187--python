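"""Shared general-linear-model machinery.

Both the voxelwise and the edgewise group comparisons are the same model: a
two-sample contrast (patients minus controls) with age, sex and total
intracranial volume (TIV) as nuisance covariates, fit independently to many
response variables (voxels or network edges) at once.  This module holds the
design-matrix construction, the vectorized OLS contrast t-statistic, and the
Freedman-Lane residual machinery used by both permutation procedures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Magnitude used in place of an infinite t when residual variance is zero
#: but the contrast is not.
T_HUGE = 1e12

DEFAULT_COVARIATES = ("age", "sex", "tiv")


@dataclass
class DesignMatrix:
    """Design for a two-sample comparison with optional nuisance covariates.

    Columns are ordered [group, intercept, covariates...] with group coded
    1 for patients and 0 for controls, so the contrast ``c = (1, 0, ...)``
    tests patients minus controls.
    """

    X: np.ndarray
    contrast: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.contrast = np.asarray(self.contrast, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("design matrix must be 2D")
        n, p = self.X.shape
        if self.contrast.shape != (p,):
            raise ValueError(f"contrast length {self.contrast.shape} != p={p}")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("design matrix is rank deficient")
        if n < p + 2:
            raise ValueError(f"need at least p+2={p + 2} subjects, got {n}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    @classmethod
    def from_phenotypes(
        cls,
        pheno: pd.DataFrame,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    ) -> "DesignMatrix":
        """Build the group-contrast design from a validated phenotype table.

        Sex is coded 0/1 (M=1); covariates are mean-centered so the
        intercept stays interpretable.  Pass ``covariates=()`` for the plain
        two-sample design.
        """
        group = (pheno["group"].to_numpy() == "patient").astype(float)
        cols = [group, np.ones(len(pheno))]
        names = ["group", "intercept"]
        for cov in covariates:
            if cov == "sex":
                v = (pheno["sex"].to_numpy() == "M").astype(float)
            else:
                v = pheno[cov].to_numpy(dtype=float)
            cols.append(v - v.mean())
            names.append(cov)
        X = np.column_stack(cols)
        contrast = np.zeros(X.shape[1])
        contrast[0] = 1.0
        return cls(X=X, contrast=contrast, columns=names)

    def reduced_design(self) -> np.ndarray:
        """Columns not involved in the contrast (the nuisance-only model)."""
        keep = self.contrast == 0
        return self.X[:, keep]


def ols_contrast_t(
    Y: np.ndarray, design: DesignMatrix, return_residuals: bool = False
):
    """Vectorized OLS contrast t-statistics.

    Parameters
    ----------
    Y : (n, m) array — one column per voxel/edge.
    design : DesignMatrix with n rows.

    Returns
    -------
    t : (m,) array of contrast t-statistics; optionally also the (n, m)
    residual matrix.

    Zero residual variance is guarded: t = 0 when the contrast estimate is
    also zero, otherwise a signed huge value (the group difference is exact).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    X, c = design.X, design.contrast
    if Y.shape[0] != design.n:
        raise ValueError(f"Y has {Y.shape[0]} rows, design has {design.n}")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / design.df_resid
    c_var = float(c @ XtX_inv @ c)
    num = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(sigma2 * c_var)
    # zero residual variance up to round-off: t is 0 when the contrast is
    # also at round-off scale, otherwise a signed huge value
    y_scale = np.einsum("ij,ij->j", Y, Y) / Y.shape[0]
    degenerate = sigma2 <= 1e-20 * np.maximum(y_scale, 1e-300)
    if np.any(degenerate):
        num_zero = np.abs(num) <= 1e-8 * np.sqrt(np.maximum(y_scale, 1e-300))
        t = np.where(degenerate & num_zero, 0.0, t)
        t = np.where(degenerate & ~num_zero, np.sign(num) * T_HUGE, t)
    if return_residuals:
        return t, resid
    return t


def freedman_lane_residuals(Y: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Residuals of the nuisance-only (reduced) model.

    Under the Freedman-Lane scheme the rows of this matrix are exchangeable
    under the null hypothesis of no group effect; permuting them and
    refitting the full model yields the permutation distribution of the
    contrast t while respecting the covariates.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    Z = design.reduced_design()
    if Z.shape[1] == 0:
        return Y.copy()
    coef, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    return Y - Z @ coef


def permutation_indices(
    n: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n) matrix of permutations of 0..n-1."""
    return np.array([rng.permutation(n) for _ in range(n_perm)])
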