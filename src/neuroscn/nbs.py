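"""Network-based statistic (NBS) for group comparison of SCN matrices.

Every unique edge of the per-subject similarity matrices is fit with the
same covariate-adjusted two-sample GLM as the voxelwise analysis.  Edges
whose t exceeds a primary threshold (default 3.1) form a graph; the maximal
connected components are the candidate subnetworks, scored by extent (edge
count).  Family-wise error over components is controlled by comparing each
observed extent with the permutation distribution of the maximum component
extent under Freedman-Lane exchange of reduced-model residuals (5,000
permutations by default, p smoothed by +1 to avoid zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .glm import DesignMatrix, freedman_lane_residuals, ols_contrast_t
from .scn import SCNMatrix


@dataclass
class EdgeStatMap:
    """Symmetric R x R matrix of edgewise contrast t-statistics."""

    t: np.ndarray
    df: int

    def __post_init__(self) -> None:
        R = self.t.shape[0]
        if self.t.shape != (R, R):
            raise ValueError("edge stat matrix must be square")
        if not np.allclose(self.t, self.t.T, equal_nan=True):
            raise ValueError("edge stat matrix must be symmetric")

    @property
    def n_roi(self) -> int:
        return self.t.shape[0]


@dataclass
class Component:
    """One suprathreshold connected subnetwork."""

    edges: list[tuple[int, int]]   # 1-based (a, b), a < b
    nodes: list[int]               # 1-based, sorted
    extent: int                    # edge count
    fwer_p: float | None = None


@dataclass
class NBSResult:
    components: list[Component]
    t_thresh: float
    direction: str
    n_perm: int
    seed: int
    edge_t: np.ndarray
    df: int
    null_max_extent: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> list[Component]:
        return [c for c in self.components if c.fwer_p is not None
                and c.fwer_p < alpha]


def _stack_edges(matrices) -> tuple[np.ndarray, int, np.ndarray, np.ndarray]:
    """(n_subjects, n_edges) matrix of unique upper-triangle edge values."""
    mats = []
    for m in matrices:
        mats.append(m.s if isinstance(m, SCNMatrix) else np.asarray(m))
    R = mats[0].shape[0]
    if any(m.shape != (R, R) for m in mats):
        raise ValueError("all SCN matrices must have the same node set")
    iu, ju = np.triu_indices(R, k=1)
    Y = np.stack([m[iu, ju] for m in mats])
    return Y, R, iu, ju


def edgewise_glm(matrices, design: DesignMatrix,
                 logit_transform: bool = False) -> EdgeStatMap:
    """Covariate-adjusted two-sample t at every unique edge.

    Similarities are used raw in (0, 1] by default; ``logit_transform``
    applies log(s / (1 - s)) first (clipped away from 1) for users worried
    about boundary compression.
    """
    Y, R, iu, ju = _stack_edges(matrices)
    if Y.shape[0] != design.n:
        raise ValueError("number of matrices does not match design rows")
    if logit_transform:
        s = np.clip(Y, 1e-12, 1 - 1e-12)
        Y = np.log(s / (1 - s))
    t_flat = ols_contrast_t(Y, design)
    t = np.zeros((R, R))
    t[iu, ju] = t_flat
    t = t + t.T
    np.fill_diagonal(t, np.nan)
    return EdgeStatMap(t=t, df=design.df_resid)


def _components_from_flat(t_flat: np.ndarray, iu: np.ndarray, ju: np.ndarray,
                          R: int, t_thresh: float, direction: str):
    """Connected components of the suprathreshold edge graph (0-based)."""
    if direction == "greater":
        keep = t_flat > t_thresh
    elif direction == "less":
        keep = t_flat < -t_thresh
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    a, b = iu[keep], ju[keep]
    if a.size == 0:
        return []
    adj = coo_matrix((np.ones(a.size), (a, b)), shape=(R, R))
    n_comp, labels = _cc(adj, directed=False)
    comps: dict[int, list[tuple[int, int]]] = {}
    for x, y in zip(a, b):
        comps.setdefault(labels[x], []).append((int(x), int(y)))
    return list(comps.values())


def _max_component_extent(t_flat, iu, ju, R, t_thresh, direction) -> int:
    comps = _components_from_flat(t_flat, iu, ju, R, t_thresh, direction)
    return max((len(c) for c in comps), default=0)


def suprathreshold_components(stats: EdgeStatMap, t_thresh: float,
                              direction: str = "greater") -> list[Component]:
    """Maximal connected components of the suprathreshold edge graph.

    Ordered by descending extent, ties broken by smallest node id; edges and
    nodes are reported 1-based to match region ids.
    """
    if t_thresh <= 0:
        raise ValueError("t_thresh must be positive")
    R = stats.n_roi
    iu, ju = np.triu_indices(R, k=1)
    t_flat = stats.t[iu, ju]
    raw = _components_from_flat(t_flat, iu, ju, R, t_thresh, direction)
    comps = []
    for edges0 in raw:
        edges = sorted((a + 1, b + 1) for a, b in edges0)
        nodes = sorted({n for e in edges for n in e})
        comps.append(Component(edges=edges, nodes=nodes, extent=len(edges)))
    comps.sort(key=lambda c: (-c.extent, c.nodes[0]))
    return comps


def nbs_compare(
    matrices,
    design: DesignMatrix,
    t_thresh: float = 3.1,
    n_perm: int = 5000,
    seed: int = 0,
    direction: str = "greater",
    logit_transform: bool = False,
) -> NBSResult:
    """Full NBS: observed components plus permutation FWER p-values.

    fwer_p = (1 + #{permutations with max extent >= observed extent})
             / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    Y, R, iu, ju = _stack_edges(matrices)
    if logit_transform:
        s = np.clip(Y, 1e-12, 1 - 1e-12)
        Y = np.log(s / (1 - s))
    t_flat = ols_contrast_t(Y, design)
    t_full = np.zeros((R, R))
    t_full[iu, ju] = t_flat
    t_full = t_full + t_full.T
    np.fill_diagonal(t_full, np.nan)
    stats_map = EdgeStatMap(t=t_full, df=design.df_resid)
    observed = suprathreshold_components(stats_map, t_thresh, direction)

    E = freedman_lane_residuals(Y, design)
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=np.int64)
    for b in range(n_perm):
        perm_t = ols_contrast_t(E[rng.permutation(design.n)], design)
        null_max[b] = _max_component_extent(perm_t, iu, ju, R, t_thresh,
                                            direction)
    for comp in observed:
        comp.fwer_p = (1 + int((null_max >= comp.extent).sum())) / (n_perm + 1)
    return NBSResult(components=observed, t_thresh=t_thresh,
                     direction=direction, n_perm=n_perm, seed=seed,
                     edge_t=t_full, df=design.df_resid,
                     null_max_extent=null_max)


def component_edge_table(result: NBSResult, roi_names: dict[int, str],
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per-edge report of significant components (node names, edge t, FWER p)."""
    rows = []
    for ci, comp in enumerate(result.significant(alpha), start=1):
        for a, b in comp.edges:
            rows.append({
                "component": ci,
                "roi_a": roi_names[a],
                "roi_b": roi_names[b],
                "edge_t": float(result.edge_t[a - 1, b - 1]),
                "component_extent": comp.extent,
                "component_fwer_p": comp.fwer_p,
            })
    return pd.DataFrame(rows, columns=["component", "roi_a", "roi_b", "edge_t",
                                       "component_extent", "component_fwer_p"])
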