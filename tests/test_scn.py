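"""KDE, symmetric KL divergence, similarity transform, matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from neuroscn import scn
from neuroscn.scn import (
    ROIDensity,
    kde_density,
    make_common_grid,
    silverman_bandwidth,
    similarity_from_kl,
    symmetric_kl,
)


def _analytic_density(mu, sd, grid, eps=1e-10):
    dens = np.maximum(stats.norm.pdf(grid, mu, sd), eps)
    dens /= np.trapezoid(dens, grid)
    return ROIDensity(roi_id=0, grid=grid, density=dens, bandwidth=sd,
                      n_values=1)


class TestKDE:
    def test_density_normalized_and_concentrated(self, rng):
        values = 0.5 + 1e-3 * rng.standard_normal(200)
        grid = np.linspace(0, 1, 512)
        d = kde_density(values, grid)
        assert abs(np.trapezoid(d.density, grid) - 1) <= 1e-3
        # mass concentrates near 0.5
        near = (grid > 0.45) & (grid < 0.55)
        assert np.trapezoid(d.density[near], grid[near]) > 0.99

    def test_kde_consistency_against_true_density(self, rng):
        values = rng.normal(0.5, 0.1, 10_000)
        grid = np.linspace(0, 1, 512)
        d = kde_density(values, grid)
        truth = stats.norm.pdf(grid, 0.5, 0.1)
        assert np.abs(d.density - truth).max() < 0.15

    def test_matches_scipy_gaussian_kde_at_same_bandwidth(self, rng):
        """Cross-check the kernel sum against an independent implementation."""
        values = rng.normal(0.4, 0.08, 400)
        grid = np.linspace(0.0, 0.8, 301)  # non-uniform-trigger: exact path
        h = silverman_bandwidth(values)
        ours = kde_density(values, grid, bandwidth=h)
        ref = stats.gaussian_kde(values, bw_method=h / values.std(ddof=1))
        assert np.allclose(ours.density, ref(grid), atol=2e-3)

    def test_deterministic(self, rng):
        values = rng.random(100)
        grid = np.linspace(-1, 2, 256)
        a = kde_density(values, grid)
        b = kde_density(values, grid)
        assert np.array_equal(a.density, b.density)
        assert a.bandwidth == b.bandwidth

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            kde_density(np.full(50, 0.3), np.linspace(0, 1, 64))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="values"):
            kde_density(np.arange(5.0), np.linspace(0, 5, 64))

    def test_bandwidth_rules(self, rng):
        v = rng.normal(size=1000)
        h_s = silverman_bandwidth(v)
        assert h_s == pytest.approx(
            0.9 * min(v.std(ddof=1),
                      np.subtract(*np.percentile(v, [75, 25])) / 1.34)
            * 1000 ** -0.2)
        d = kde_density(v, np.linspace(-5, 5, 128), bandwidth="fixed:0.3")
        assert d.bandwidth == 0.3


class TestSymmetricKL:
    def test_identity_is_zero(self):
        grid = np.linspace(-6, 6, 512)
        p = _analytic_density(0, 1, grid)
        assert symmetric_kl(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        grid = np.linspace(-6, 7, 512)
        p = _analytic_density(0, 1, grid)
        q = _analytic_density(1, 1.3, grid)
        assert symmetric_kl(p, q) == pytest.approx(symmetric_kl(q, p),
                                                   abs=1e-12)

    def test_gaussian_closed_form_quadrature(self):
        """Analytic N(0,1) vs N(1,1) densities: symmetric KL = 1.0 exactly;
        quadrature on 512 points over +-6 SD must agree to 1e-3."""
        grid = np.linspace(-6, 7, 512)
        p = _analytic_density(0, 1, grid)
        q = _analytic_density(1, 1, grid)
        assert symmetric_kl(p, q) == pytest.approx(1.0, abs=1e-3)

    def test_general_gaussian_closed_form(self):
        """KL(N1||N2) = ln(s2/s1) + (s1^2 + (m1-m2)^2) / (2 s2^2) - 1/2."""
        m1, s1, m2, s2 = 0.2, 0.8, -0.5, 1.4
        grid = np.linspace(-9, 9, 2048)
        p = _analytic_density(m1, s1, grid)
        q = _analytic_density(m2, s2, grid)
        kl = lambda ma, sa, mb, sb: (np.log(sb / sa)
                                     + (sa ** 2 + (ma - mb) ** 2) / (2 * sb ** 2)
                                     - 0.5)
        expected = kl(m1, s1, m2, s2) + kl(m2, s2, m1, s1)
        assert symmetric_kl(p, q) == pytest.approx(expected, abs=2e-3)

    def test_mismatched_grids_rejected(self):
        p = _analytic_density(0, 1, np.linspace(-6, 6, 128))
        q = _analytic_density(0, 1, np.linspace(-5, 6, 128))
        with pytest.raises(ValueError, match="grid"):
            symmetric_kl(p, q)


class TestSimilarity:
    def test_closed_form_values(self):
        assert similarity_from_kl(0.0) == 1.0
        assert similarity_from_kl(1.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_negative_divergence_rejected(self):
        with pytest.raises(ValueError):
            similarity_from_kl(-0.1)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=200.0),
           st.floats(min_value=0.0, max_value=200.0))
    def test_strictly_decreasing_and_bounded(self, d1, d2):
        s1, s2 = similarity_from_kl(d1), similarity_from_kl(d2)
        assert 0.0 < s1 <= 1.0
        if d1 < d2:
            assert s1 >= s2
        if d2 - d1 > 1e-12:
            assert s1 > s2


class TestBuildSCN:
    def test_roi_extraction_counts_and_errors(self, tiny_cohort):
        vol = tiny_cohort.volumes[0]
        parc = tiny_cohort.parcellation
        values = scn.extract_roi_values(vol, parc, 1)
        assert len(values) == int((parc.labels == 1).sum())
        with pytest.raises(ValueError, match="roi_id"):
            scn.extract_roi_values(vol, parc, 99)
        with pytest.raises(ValueError, match="ROI 1"):
            scn.extract_roi_values(vol, parc, 1,
                                   mask=np.zeros(parc.shape, bool))

    def test_identical_rois_have_unit_similarity(self, tiny_cohort):
        """Two regions carrying the same value multiset get s = 1."""
        vol = tiny_cohort.volumes[0]
        parc = tiny_cohort.parcellation
        v1 = scn.extract_roi_values(vol, parc, 1)
        grid = make_common_grid(vol, parc)
        d1 = kde_density(v1, grid, roi_id=1)
        d2 = kde_density(np.random.default_rng(0).permutation(v1), grid,
                         roi_id=2)
        assert similarity_from_kl(symmetric_kl(d1, d2)) == pytest.approx(1.0)

    def test_matrix_invariants(self, tiny_cohort):
        mat = scn.build_scn(tiny_cohort.volumes[0], tiny_cohort.parcellation)
        s = mat.s
        assert s.shape == (12, 12)
        assert np.allclose(s, s.T)
        assert np.allclose(np.diag(s), 1.0)
        off = s[~np.eye(12, dtype=bool)]
        assert np.all((off > 0) & (off <= 1))

    def test_voxel_order_irrelevant(self, tiny_cohort, rng):
        """Shuffling voxel values within regions leaves the matrix unchanged."""
        vol = tiny_cohort.volumes[1]
        parc = tiny_cohort.parcellation
        ref = scn.build_scn(vol, parc)
        shuffled = vol.data.copy()
        for roi_id in range(1, parc.n_roi + 1):
            m = parc.labels == roi_id
            shuffled[m] = rng.permutation(shuffled[m])
        vol2 = type(vol)(vol.subject_id, shuffled, vol.affine)
        assert np.allclose(scn.build_scn(vol2, parc).s, ref.s, atol=1e-12)

    def test_pairwise_kl_matches_scalar_route(self, tiny_cohort):
        """The vectorized all-pairs computation equals pairwise calls."""
        vol = tiny_cohort.volumes[2]
        parc = tiny_cohort.parcellation
        mat = scn.build_scn(vol, parc)
        grid = make_common_grid(vol, parc)
        dens = [kde_density(scn.extract_roi_values(vol, parc, r), grid,
                            roi_id=r) for r in (1, 4, 9)]
        for i, a in enumerate((1, 4, 9)):
            for j, b in enumerate((1, 4, 9)):
                if i < j:
                    expected = similarity_from_kl(
                        symmetric_kl(dens[i], dens[j]))
                    assert mat.s[a - 1, b - 1] == pytest.approx(expected,
                                                                abs=1e-9)

    def test_pearson_variant_runs(self, tiny_cohort):
        mat = scn.build_scn(tiny_cohort.volumes[0], tiny_cohort.parcellation,
                            method="pearson")
        assert np.allclose(np.diag(mat.s), 1.0)
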