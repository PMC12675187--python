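# Methods

`neuroscn` implements a case-control analysis pipeline for registered,
segmented gray-matter volume (GMV) images: voxel-based morphometry (VBM)
group statistics with cluster-level correction, individual structural
covariance networks (SCN) built from regional kernel density estimates
compared by symmetric Kullback–Leibler divergence, network-based-statistic
(NBS) group inference over those networks, and covariate-adjusted symptom
correlations.  A synthetic-cohort generator with a ground-truth ledger
closes the loop: every statistical claim the package makes is validated by
false-positive calibration and planted-effect recovery on simulated data.

## The models

### Voxelwise group GLM and cluster inference

At every voxel inside the analysis mask (mean GMV above 0.1 of the robust
maximum, non-zero variance) an ordinary least squares model is fit with
columns [group, intercept, age, sex, TIV], and the group contrast
(patients − controls) is converted to a t-statistic with ν = n − p degrees
of freedom.  Cluster-forming uses the height threshold u = t₁₋ₚ(ν) at
voxel p < 0.001; suprathreshold voxels are grouped by 18-connectivity
(configurable to 6/26).  Both one-sided maps are analyzed separately and
clusters carry their signed peak t and the peak's world-mm coordinates
(single global peak, ties broken by lexicographic voxel index).

Two corrected cluster p-values are available:

* **Random-field theory.**  Smoothness is estimated from voxelwise-
  standardized residuals: λᵢ is the mean squared forward-difference
  derivative along axis i, FWHMᵢ = √(4 ln 2 / λᵢ), resels-per-voxel =
  voxel volume / ∏FWHM.  The expected cluster count is E[m] = R·ρ₃(u)
  with the 3D Euler-characteristic density of a t-field, the expected
  suprathreshold volume E[N] = R·P(T > u), cluster sizes follow
  P(size ≥ k) = exp(−β k^{2/3}) with β = (Γ(5/2)·E[m]/E[N])^{2/3}, and
  the corrected p is 1 − exp(−E[m]·P(size ≥ k)).
* **Permutation (the calibration reference).**  Freedman–Lane: the
  reduced (nuisance-only) model residuals are row-permuted and the full
  model refit; the null distribution is the maximum cluster extent over
  permutations, and each observed cluster's corrected p is the +1-smoothed
  exceedance proportion.

A cluster is reported when its corrected p is below the cluster threshold
(default 0.05) **and** its extent strictly exceeds the voxel-count floor
(default 200 voxels at 1.5 mm-scale grids; tests on the 3 mm desk grid use
the volume-equivalent 20).  RFT on small coarse grids is approximate —
the validation suite allows its family-wise error to sit between the
binomial bands around 0.05 and 0.10, while the permutation route must sit
in the band around 0.05.

The residual field of the synthetic cohorts is not strictly a smooth
Gaussian field: subject-level regional offsets are piecewise constant over
regions, which the derivative-based estimator reads as additional
smoothness.  This is a genuine property of the field (the permutation
route is exact regardless) and is one reason the RFT band is wider.

### Individual structural covariance networks

For one subject, the voxel values of each atlas region are summarized by a
Gaussian KDE

    p̂(x) = (1 / (n h)) Σᵢ φ((x − vᵢ) / h)

evaluated on a grid of G = 512 points shared by all regions of that
subject (KL divergence needs common support).  The grid spans the pooled
in-brain value range padded by 3 pooled SDs.  The bandwidth rule is
Silverman's, h = 0.9·min(SD, IQR/1.34)·n^{−1/5} (Scott and fixed-h are
config options).  Densities are floored at ε = 1e−10 before any
logarithm — otherwise disjoint supports give infinite divergence — and
renormalized to trapezoid-integrate to one.

Region pairs are compared by the symmetric KL divergence
D = KL(P‖Q) + KL(Q‖P) (the sum, not the mean) computed by trapezoid
quadrature, and mapped to a similarity s = exp(−D) ∈ (0, 1]; s = 1 iff the
densities coincide on the grid.  The R×R matrix of similarities with unit
diagonal is the subject's SCN.  exp(−D) is the established transform in
the individual-SCN literature; nothing downstream depends on its exact
form beyond strict monotonicity.  A Pearson-on-density-sequences variant
(`method="pearson"`) is exposed for comparison but is not the default and
does not share the KL network's interpretation.

On the uniform evaluation grid the kernel sum is computed by exact linear
binning followed by a discrete Gaussian filter whenever the bandwidth
spans at least 5 grid steps; this is numerically indistinguishable from
the direct sum (≈3e−4 in density, ≈7e−4 in similarity — inside the 1e−3
grid-refinement stability budget) and an order of magnitude faster.  The
direct sum is used otherwise and remains the reference implementation.

### Network-based statistic

Each unique edge of the per-subject SCN matrices is fit with the same
covariate-adjusted group GLM (similarities used raw in (0, 1]; an optional
logit transform exists, default off).  Edges with t beyond the primary
threshold (default 3.1, applied per direction) form a graph whose maximal
connected components are scored by extent (edge count).  Family-wise error
over components is controlled by the permutation distribution of the
maximum component extent under Freedman–Lane exchange (default 5,000
permutations; +1 smoothing so p ≥ 1/(n_perm+1)).  The two directions are
analyzed separately, mirroring the hyper-/hypo-covariance split of a group
comparison.

### Clinical associations and demographics

Post-hoc associations use partial Pearson correlation: both variables are
residualized on [1, age, sex, TIV] and the residual correlation is tested
with df = n − 2 − #covariates.  Families of p-values are adjusted by
Benjamini–Hochberg; both raw p and q are always reported.  Signal
extraction supports differential-cluster means and 8 mm-sphere means
(voxel-center-within-radius membership) for the sensitivity analysis.
Demographic comparisons use Pearson's chi-square without continuity
correction (df = 1) and two-sample t-tests (pooled or Welch).

## The synthetic cohort

The generator emulates what enters the pipeline after segmentation and
registration — not raw MRI.  On an ellipsoidal "brain" mask partitioned
into R Voronoi regions (seed points sampled uniformly; every region must
reach 10 voxels), a subject's voxel value inside region r is

    baseline_r + Δ_r·1[patient] + age_slope·(age − 19)
    + sex_effect·1[male] + global_offset + latent_r + smooth noise,

clipped at zero.  Parameters (defaults in parentheses):

* grid 32×38×32 at 3 mm (desk scale; a 64×76×64 / 1.5 mm configuration is
  used where the literal 200-voxel extent rule is exercised), 90 regions,
  30+30 subjects; the full-scale preset mirrors a 159/121 cohort.
* `baseline_mean` (0.55), `baseline_sd` (0.01): per-region mean GMV levels
  shared by all subjects.  Baselines are kept nearly homogeneous so that
  pairwise similarities occupy the sensitive mid-range of exp(−D) rather
  than saturating near zero for distant region pairs.
* `noise_sd` (0.06), `noise_fwhm_mm` (3): white voxel noise convolved to
  the stated FWHM and rescaled, the within-region spread that the KDEs
  estimate.  The intrinsic correlation length is kept at one voxel so a
  ~160-voxel region contributes roughly that many effective samples; the
  analysis-side 6 mm smoothing is applied by the VBM stage itself.
* `latent_sd` (0.05): per-subject, per-region mean offsets — the
  between-subject variability of regional GMV, and the carrier of the
  planted coupling.
* `age_slope` (−0.003/y), `sex_effect` (0.02), `global_sd` (0.01): linear
  covariate structure; TIV is the subject's summed GMV with 2%
  multiplicative noise, so the TIV covariate genuinely tracks global
  volume.
* Couplings: for an edge (a, b, ρ) active in a subject's group, the
  region offsets are drawn with correlation-by-sharing,
  latent_b = ρ·latent_a + √(1−ρ²)·independent.  Sharing is transitive: a
  connected planted subnetwork correlates *all* node pairs at products of
  the planted ρ, so the ground-truth ledger records every pair with
  implied correlation ≥ 0.5 (`implied_coupling`), and recovery is scored
  against that set.
* Symptom score: patients receive round(22.6 + β·z + noise) clipped to
  [0, 52], where z is the standardized planted driver — for an edge tie,
  −|latent_a − latent_b| (monotone proxy of that edge's similarity).  The
  22.6/5.69 location/scale echoes a typical moderate-depression HAMD-17
  distribution and is cosmetic.

Preset-specific choices, made once at design time:

* **regional** (VBM recovery): 36 regions (~400 voxels each at desk
  scale) and `latent_sd` = 0.02.  This preset emulates a regional
  atrophy/hypertrophy contrast in which between-subject variability is
  voxel-level; a large shared regional offset is the *coupled* preset's
  mechanism, and at 30+30 it would impose ±30% group-mean noise on a
  planted 0.5 SD effect, turning single-cohort recovery into a coin flip
  for any method.  Planted effect sizes quoted "in SD units" refer to the
  analytic between-subject voxel SD (`SimulationConfig.subject_sd`).
* **coupled** (NBS recovery) and **hamd**: 45 regions.  The component
  search's multiplicity burden grows with the node count, and a
  four-region planted subnetwork caps the observable component at 6 edges;
  at 90 nodes the permutation null's maximum component extent (95th
  percentile ≈ 7–10 edges, further inflated because the planted variance
  itself enters the permuted residuals) exceeds that ceiling, so no
  parameterization of the coupling mechanism can be detected reliably.
  At 45 nodes the planted subnetwork is recovered robustly.  The desk
  preset used for matrix invariants and null calibration keeps 90 regions.

What the generator does **not** emulate: cortical anatomy and realistic
region geometry, partial-volume effects, scanner artifacts and site
effects, non-Gaussian and spatially non-stationary noise, registration
error, and the wide inter-regional heterogeneity of real GM distributions.
Passing recovery tests therefore demonstrates that the estimators detect
the mechanisms they target at realistic effect-to-noise ratios — not that
real cohorts of this size would yield the same power.

## Validation sizes and numerical choices

The test suite runs at desk scale: NBS family-wise error over 100 null
cohorts at 500 permutations each; NBS recovery over 50 coupled cohorts;
VBM null calibration over 40 (RFT) and 20 (permutation, 200 permutations)
cohorts; VBM recovery over 5 cohorts plus one 1.5 mm-grid run.  All
binomial acceptance bands are exact intervals computed at the replicate
counts actually run.  The acceptance script repeats the same computations
at slightly smaller replication driven by a single seed.

Degenerate cases: zero residual variance yields t = 0 when the contrast
estimate is also at round-off scale and a signed huge value otherwise;
KDE requires ≥ 10 values and non-zero variance; permutation p-values are
+1-smoothed; component ordering is deterministic (descending extent, then
smallest node id); cluster peak ties break on the first voxel in
lexicographic index order.  Volumes and parcellations must share a grid
exactly — nothing is ever resampled implicitly.

## Known limitations

* RFT cluster p-values are approximate on coarse grids and piecewise-
  constant latent structure; the permutation route is authoritative.
* The extent-based NBS cannot detect planted subnetworks whose edge count
  is small relative to the null maximum component extent at the chosen
  node count; this is a property of the statistic, not of the
  implementation.  At the coupled preset's conditions the recovery suite
  measures a ~72% per-replicate recovery rate (36/50): a four-node
  subnetwork caps the observable component at 6 edges, a component of
  only 3 suprathreshold truth edges sits at permutation p ≈ 0.06–0.08
  (never significant at 0.05), and occasional chance neighbor edges dilute
  the Jaccard overlap of an otherwise-correct detection.  Building the
  networks from pre-smoothed volumes lowers recovery further (spatial
  smoothing trades within-region sample size for saturation of the
  similarity scale) and is deliberately not done.
* Similarities near 1 compress group differences (bounded scale); the
  logit option mitigates this but is off by default.
* The generator's couplings act through region-mean offsets only; richer
  dependence (shape, variance coupling) would not be detected more easily
  by the KL similarity, but is not modelled.
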