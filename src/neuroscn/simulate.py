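"""Synthetic two-group cohort generator with known ground truth.

Emulates the data a structural-MRI case-control study feeds into the
pipeline: per-subject gray-matter volumes on a shared grid, an ROI
parcellation standing in for an anatomical atlas, and a phenotype table
(group, age, sex, TIV, symptom score).  Effects are planted explicitly:

* regional mean gray-matter shifts in the patient group (both signs),
* group-specific inter-regional coupling of per-subject ROI mean offsets
  (``latent_b = rho * latent_a + sqrt(1 - rho^2) * independent``), the
  minimal mechanism a distribution-similarity network statistic can detect,
* linear age/sex/global-volume covariate effects,
* a symptom score (HAMD-17-like) tied linearly to a planted edge or region.

Everything is reproducible from a single integer seed; a
:class:`GroundTruth` ledger records what was planted for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .types import GMVolume, MIN_ROI_VOXELS, Parcellation, validate_phenotypes

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Population mean age (years) used as the centering constant for the age
#: slope, so a subject's volume depends only on its own phenotype row.
AGE_CENTER = 19.0


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults are the desk-scale preset: 30+30 subjects on a 32x38x32 grid of
    3 mm voxels with 90 regions, matching the scale of the analyses the
    package is validated on; ``full_preset`` mirrors a 159-patient /
    121-control study.
    """

    n_patients: int = 30
    n_controls: int = 30
    grid_shape: tuple[int, int, int] = (32, 38, 32)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_roi: int = 90
    noise_fwhm_mm: float = 3.0
    noise_sd: float = 0.06
    baseline_mean: float = 0.55
    baseline_sd: float = 0.01
    latent_sd: float = 0.05
    global_sd: float = 0.01
    age_slope: float = -0.003
    sex_effect: float = 0.02
    tiv_noise: float = 0.02
    regional_effects: tuple[tuple[int, float], ...] = ()
    coupled_edges: tuple[tuple[int, int, float, str], ...] = ()
    hamd_edge: tuple[int, int, float, float] | None = None
    hamd_roi: tuple[int, float, float] | None = None
    hamd_mean: float = 22.6
    hamd_sd: float = 5.69
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        for a, b, rho, grp in self.coupled_edges:
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"coupling rho must be in [0, 1], got {rho}")
            if grp not in ("patient", "control", "both"):
                raise ValueError(f"unknown coupling group {grp!r}")
            for r in (a, b):
                if not 1 <= r <= self.n_roi:
                    raise ValueError(f"coupled edge names invalid ROI {r}")
        for r, _ in self.regional_effects:
            if not 1 <= r <= self.n_roi:
                raise ValueError(f"regional effect names invalid ROI {r}")

    def subject_sd(self) -> float:
        """Analytic between-subject SD of a voxel under the null pieces.

        Combines the independent subject-level variance sources: ROI latent
        offset, global offset, smooth noise, age slope (age SD ~5 y) and the
        sex split.  Regional effect sizes quoted "in SD units" refer to this
        quantity.
        """
        return float(np.sqrt(
            self.latent_sd ** 2
            + self.global_sd ** 2
            + self.noise_sd ** 2
            + (self.age_slope * 5.0) ** 2
            + (self.sex_effect / 2.0) ** 2
        ))


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    config: SimulationConfig
    affected_rois: list[tuple[int, float]]
    affected_voxel_mask: np.ndarray
    coupled_edges: list[tuple[int, int, float, str]]
    #: every ROI pair with implied latent correlation >= 0.5 (includes pairs
    #: correlated transitively through shared latents), with that correlation
    coupled_pairs: dict[tuple[int, int], float]
    latents: pd.DataFrame          # subjects x ROIs, per-subject mean offsets
    hamd_driver: pd.Series | None  # per-patient planted quantity (z-scored)


@dataclass
class Cohort:
    volumes: list[GMVolume]
    parcellation: Parcellation
    phenotypes: pd.DataFrame
    ground_truth: GroundTruth


def _ellipsoid_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Central ellipsoidal 'brain' mask with semi-axes 0.46 * extent."""
    coords = np.indices(grid_shape, dtype=float)
    out = np.zeros(grid_shape, dtype=bool)
    center = (np.asarray(grid_shape, dtype=float) - 1.0) / 2.0
    semi = 0.46 * (np.asarray(grid_shape, dtype=float) - 1.0)
    norm2 = sum(((coords[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    out[norm2 <= 1.0] = True
    return out


def _centered_affine(grid_shape, voxel_size_mm) -> np.ndarray:
    """RAS affine with isocenter at the grid center."""
    vox = np.asarray(voxel_size_mm, dtype=float)
    affine = np.diag([*vox, 1.0])
    affine[:3, 3] = -vox * (np.asarray(grid_shape) - 1) / 2.0
    return affine


def generate_parcellation(
    grid_shape: tuple[int, int, int],
    n_roi: int = 90,
    seed: int = 0,
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    min_roi_voxels: int = MIN_ROI_VOXELS,
    max_tries: int = 20,
) -> Parcellation:
    """Voronoi-style partition of an ellipsoidal brain mask into ``n_roi`` regions.

    Seed points are sampled uniformly from the mask; every mask voxel joins
    its nearest seed.  Deterministic for a fixed seed.  Raises if the grid
    cannot host ``n_roi`` regions of at least ``min_roi_voxels`` voxels.
    """
    if n_roi < 2:
        raise ValueError("n_roi must be >= 2")
    mask = _ellipsoid_mask(grid_shape)
    n_mask = int(mask.sum())
    if n_mask < n_roi * min_roi_voxels:
        raise ValueError(
            f"grid {grid_shape} has {n_mask} brain voxels; cannot host "
            f"{n_roi} regions of >= {min_roi_voxels} voxels"
        )
    rng = np.random.default_rng([seed, 0x9A7C])
    vox_ijk = np.argwhere(mask)
    for _ in range(max_tries):
        pick = rng.choice(n_mask, size=n_roi, replace=False)
        seeds = vox_ijk[pick].astype(float)
        # nearest seed in mm so anisotropic voxels partition isotropically
        scale = np.asarray(voxel_size_mm, dtype=float)
        _, nearest = cKDTree(seeds * scale).query(vox_ijk * scale, k=1)
        labels = np.zeros(grid_shape, dtype=np.int64)
        labels[mask] = nearest + 1
        counts = np.bincount(labels.ravel(), minlength=n_roi + 1)[1:]
        if counts.min() >= min_roi_voxels:
            names = {i: f"roi_{i:03d}" for i in range(1, n_roi + 1)}
            return Parcellation(
                labels=labels,
                roi_names=names,
                affine=_centered_affine(grid_shape, voxel_size_mm),
                min_roi_voxels=min_roi_voxels,
            )
    raise ValueError(
        f"could not place {n_roi} regions of >= {min_roi_voxels} voxels "
        f"on grid {grid_shape} after {max_tries} attempts"
    )


def _smooth_noise(rng: np.random.Generator, grid_shape, voxel_size_mm,
                  fwhm_mm: float, sd: float) -> np.ndarray:
    """White noise convolved to the stated FWHM, rescaled to SD ``sd``."""
    w = rng.standard_normal(grid_shape)
    if fwhm_mm <= 0:
        return sd * w
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / np.asarray(voxel_size_mm, dtype=float)
    f = ndimage.gaussian_filter(w, sigma=sigma_vox, mode="constant")
    return sd * f / f.std()


def _subject_latents(config: SimulationConfig, group: str,
                     rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Per-subject ROI mean offsets with coupling-by-sharing, plus global offset.

    The RNG stream consumes the same number of draws regardless of group, so
    patient and control cohorts differ only through the planted structure.
    """
    eps = rng.standard_normal(config.n_roi)
    global_off = float(rng.standard_normal()) * config.global_sd
    latents = config.latent_sd * eps.copy()
    assigned: set[int] = set()
    for a, b, rho, grp in config.coupled_edges:
        active = grp == "both" or grp == group
        if not active:
            continue
        ia, ib = a - 1, b - 1
        if ia in assigned and ib in assigned:
            continue  # correlation already induced transitively
        if ib in assigned and ia not in assigned:
            ia, ib = ib, ia
        latents[ib] = rho * latents[ia] + np.sqrt(1 - rho ** 2) * (
            config.latent_sd * eps[ib]
        )
        assigned.update((ia, ib))
    return latents, global_off


def generate_subject(
    parc: Parcellation,
    row: pd.Series | dict,
    config: SimulationConfig,
    subject_seed: int,
    return_latents: bool = False,
):
    """One subject's gray-matter volume given its phenotype row.

    Voxel value inside region r:

        baseline_r + delta_r * 1[patient] + age_slope * (age - 19)
        + sex_effect * 1[male] + global_offset + latent_r + smooth noise,

    clipped at 0; background voxels are 0.  Baselines are shared across the
    cohort (derived from ``config.seed``); latents and noise come from the
    per-subject seed.
    """
    rng_base = np.random.default_rng([config.seed, 0xBA5E])
    baselines = config.baseline_mean + config.baseline_sd * rng_base.standard_normal(
        config.n_roi
    )
    rng = np.random.default_rng([config.seed, 0x5B17, subject_seed])
    group = row["group"]
    latents, global_off = _subject_latents(config, group, rng)

    roi_value = baselines + latents
    if group == "patient":
        for roi_id, delta in config.regional_effects:
            roi_value[roi_id - 1] += delta
    subject_shift = (
        config.age_slope * (float(row["age"]) - AGE_CENTER)
        + config.sex_effect * (1.0 if row["sex"] == "M" else 0.0)
        + global_off
    )

    data = np.zeros(parc.shape, dtype=np.float64)
    inside = parc.labels > 0
    data[inside] = roi_value[parc.labels[inside] - 1] + subject_shift
    data += _smooth_noise(rng, parc.shape, config.voxel_size_mm,
                          config.noise_fwhm_mm, config.noise_sd)
    data[~inside] = 0.0
    np.clip(data, 0.0, None, out=data)
    vol = GMVolume(subject_id=str(row["subject_id"]), data=data,
                   affine=parc.affine)
    if return_latents:
        return vol, latents
    return vol


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Full synthetic cohort: volumes, parcellation, phenotypes, ground truth.

    Ages ~ Normal(19, 5) truncated at 12, sex ~ Bernoulli(1/2); TIV is the
    subject's total gray-matter volume (mm^3) with small multiplicative
    noise; the symptom score is built for patients from the planted driver
    (edge and/or region) plus noise, rounded and clipped to [0, 52].
    """
    parc = generate_parcellation(
        config.grid_shape, config.n_roi, seed=config.seed,
        voxel_size_mm=config.voxel_size_mm,
    )
    n = config.n_patients + config.n_controls
    rng_pheno = np.random.default_rng([config.seed, 0xA6E5])
    ages = 19.0 + 5.0 * rng_pheno.standard_normal(n)
    while np.any(ages < 12.0):  # truncated normal by redraw
        bad = ages < 12.0
        ages[bad] = 19.0 + 5.0 * rng_pheno.standard_normal(int(bad.sum()))
    sexes = np.where(rng_pheno.random(n) < 0.5, "M", "F")
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    pheno = pd.DataFrame({
        "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
        "group": groups,
        "age": np.round(ages, 1),
        "sex": sexes,
        "tiv": np.nan,
        "hamd17": np.nan,
    })

    volumes: list[GMVolume] = []
    latents_rows = []
    voxel_volume = float(np.prod(config.voxel_size_mm))
    rng_tiv = np.random.default_rng([config.seed, 0x71F])
    for i, row in pheno.iterrows():
        vol, latents = generate_subject(parc, row, config, subject_seed=i,
                                        return_latents=True)
        volumes.append(vol)
        latents_rows.append(latents)
        pheno.loc[i, "tiv"] = vol.data.sum() * voxel_volume * (
            1.0 + config.tiv_noise * rng_tiv.standard_normal()
        )
    latents_df = pd.DataFrame(
        np.vstack(latents_rows),
        index=pheno["subject_id"],
        columns=[f"roi_{r:03d}" for r in range(1, config.n_roi + 1)],
    )

    # symptom score for patients
    rng_hamd = np.random.default_rng([config.seed, 0x4A3D])
    is_pat = pheno["group"].to_numpy() == "patient"
    lat_pat = latents_df.to_numpy()[is_pat]
    score = np.full(is_pat.sum(), config.hamd_mean)
    driver = None
    noise_sd = config.hamd_sd
    if config.hamd_edge is not None:
        a, b, beta, noise_sd = config.hamd_edge
        q = -np.abs(lat_pat[:, a - 1] - lat_pat[:, b - 1])
        driver = (q - q.mean()) / q.std()
        score = score + beta * driver
    if config.hamd_roi is not None:
        r, beta_r, noise_r = config.hamd_roi
        q = lat_pat[:, r - 1]
        z = (q - q.mean()) / q.std()
        score = score + beta_r * z
        if config.hamd_edge is None:
            driver, noise_sd = z, noise_r
    score = score + noise_sd * rng_hamd.standard_normal(len(score))
    pheno.loc[is_pat, "hamd17"] = np.clip(np.round(score), 0, 52)

    affected_mask = np.zeros(parc.shape, dtype=bool)
    for roi_id, _ in config.regional_effects:
        affected_mask |= parc.labels == roi_id
    gt = GroundTruth(
        config=config,
        affected_rois=list(config.regional_effects),
        affected_voxel_mask=affected_mask,
        coupled_edges=list(config.coupled_edges),
        coupled_pairs=implied_coupling(config),
        latents=latents_df,
        hamd_driver=None if driver is None else pd.Series(
            driver, index=pheno.loc[is_pat, "subject_id"]
        ),
    )
    return Cohort(volumes=volumes, parcellation=parc,
                  phenotypes=validate_phenotypes(pheno), ground_truth=gt)


# ---------------------------------------------------------------------------
# Presets


def null_preset(seed: int = 0, **overrides) -> SimulationConfig:
    """No planted effects: every downstream positive is a false positive."""
    return replace(SimulationConfig(seed=seed), **overrides)


def regional_preset(seed: int = 0, delta_sd: float = 0.5,
                    roi_id: int = 7, **overrides) -> SimulationConfig:
    """One region's mean shifted by ``delta_sd`` subject-level SDs in patients.

    Uses 36 regions so each spans ~400 voxels on the desk grid, giving the
    cluster pipeline a spatially extended target.  The subject-level regional
    offset scale is reduced relative to the cohort default: this preset
    emulates a regional atrophy/hypertrophy contrast where between-subject
    variability is dominated by voxel noise, whereas large shared regional
    offsets are the distinct mechanism of the coupled preset.
    """
    base = SimulationConfig(seed=seed, n_roi=36, latent_sd=0.02)
    delta = delta_sd * base.subject_sd()
    return replace(base, regional_effects=((roi_id, delta),), **overrides)


#: The planted 4-edge subnetwork among 4 regions used by the coupled preset.
COUPLED_SUBNETWORK = ((5, 12), (5, 23), (5, 42), (12, 23))


def implied_coupling(config: SimulationConfig, group: str = "patient",
                     min_corr: float = 0.5) -> dict[tuple[int, int], float]:
    """Pairwise latent correlations implied by the sharing rules.

    Coupling-by-sharing makes correlation transitive: planting rho on edges
    (a, b) and (b, c) also correlates (a, c) at rho^2.  Recovery tests score
    against every pair whose implied correlation reaches ``min_corr``, not
    just the listed edges, because those pairs genuinely covary.
    """
    R = config.n_roi
    A = np.eye(R) * config.latent_sd  # latent = A @ eps
    assigned: set[int] = set()
    for a, b, rho, grp in config.coupled_edges:
        if not (grp == "both" or grp == group):
            continue
        ia, ib = a - 1, b - 1
        if ia in assigned and ib in assigned:
            continue
        if ib in assigned and ia not in assigned:
            ia, ib = ib, ia
        new_row = rho * A[ia].copy()
        new_row[ib] += np.sqrt(1 - rho ** 2) * config.latent_sd
        A[ib] = new_row
        assigned.update((ia, ib))
    cov = A @ A.T
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    out = {}
    for i in range(R):
        for j in range(i + 1, R):
            if corr[i, j] >= min_corr:
                out[(i + 1, j + 1)] = float(corr[i, j])
    return out


def coupled_preset(seed: int = 0, rho: float = 0.9, **overrides) -> SimulationConfig:
    """Patient-only inter-regional coupling on a 4-edge subnetwork.

    Uses 45 regions: the multiplicity burden of a component search scales
    with the node count, and a four-region planted subnetwork is the scale
    of signal this preset is meant to probe.
    """
    edges = tuple((a, b, rho, "patient") for a, b in COUPLED_SUBNETWORK)
    return replace(SimulationConfig(seed=seed, n_roi=45),
                   coupled_edges=edges, **overrides)


def hamd_preset(seed: int = 0, beta: float = 3.5, **overrides) -> SimulationConfig:
    """Symptom score tied to a planted edge, 100 patients for association tests."""
    cfg = SimulationConfig(
        seed=seed, n_patients=100, n_controls=10, n_roi=45,
        coupled_edges=((5, 12, 0.5, "both"),),
        hamd_edge=(5, 12, beta, 4.5),
    )
    return replace(cfg, **overrides)


def full_preset(seed: int = 0, **overrides) -> SimulationConfig:
    """Cohort sized like a 159-patient / 121-control study."""
    return replace(SimulationConfig(seed=seed, n_patients=159, n_controls=121),
                   **overrides)


PRESETS = {
    "null": null_preset,
    "regional": regional_preset,
    "coupled": coupled_preset,
    "hamd": hamd_preset,
    "full": full_preset,
}
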