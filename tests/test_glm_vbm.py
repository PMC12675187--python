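"""Design matrix, voxelwise GLM, smoothing, smoothness, cluster inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from neuroscn import simulate, vbm
from neuroscn.glm import DesignMatrix, freedman_lane_residuals, ols_contrast_t
from neuroscn.types import GMVolume, validate_phenotypes


def _group_only_design(n_a, n_b):
    group = np.r_[np.ones(n_a), np.zeros(n_b)]
    X = np.column_stack([group, np.ones(n_a + n_b)])
    return DesignMatrix(X=X, contrast=np.array([1.0, 0.0]),
                        columns=["group", "intercept"])


class TestGLM:
    def test_matches_pooled_two_sample_t_closed_form(self):
        """[1,2,3] vs [2,3,4] with a group-only design: t = -1.2247."""
        d = _group_only_design(3, 3)
        t = ols_contrast_t(np.array([[1, 2, 3, 2, 3, 4]], dtype=float).T, d)
        assert t[0] == pytest.approx(-np.sqrt(1.5), abs=1e-10)

    def test_equals_scipy_ttest_on_random_data(self, rng):
        d = _group_only_design(8, 11)
        Y = rng.standard_normal((19, 40))
        t = ols_contrast_t(Y, d)
        ref = stats.ttest_ind(Y[:8], Y[8:], equal_var=True).statistic
        assert np.allclose(t, ref, atol=1e-10)

    def test_degenerate_variance_guarded(self):
        d = _group_only_design(3, 3)
        Y = np.array([[1, 1, 1, 2, 2, 2], [3, 3, 3, 3, 3, 3]], dtype=float).T
        t = ols_contrast_t(Y, d)
        assert np.isfinite(t).all()
        assert abs(t[0]) > 1e10     # exact separation: huge, finite
        assert np.sign(t[0]) == -1  # patients lower than controls
        assert t[1] == 0.0          # identical groups: zero

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(X=X, contrast=np.array([1.0, 0.0]),
                         columns=["a", "b"])

    def test_from_phenotypes_columns(self):
        df = validate_phenotypes(pd.DataFrame({
            "subject_id": list("abcdefgh"),
            "group": ["patient"] * 4 + ["control"] * 4,
            "age": [20, 25, 30, 22, 24, 28, 21, 26],
            "sex": ["M", "F", "M", "F", "M", "F", "M", "F"],
            "tiv": [1.1e6, 1.2e6, 1.0e6, 1.15e6, 1.05e6, 1.25e6, 1.08e6,
                    1.18e6],
        }))
        d = DesignMatrix.from_phenotypes(df)
        assert d.columns == ["group", "intercept", "age", "sex", "tiv"]
        assert d.X[:, 0].tolist() == [1, 1, 1, 1, 0, 0, 0, 0]
        assert d.df_resid == 3

    def test_freedman_lane_residuals_orthogonal_to_nuisance(self, rng):
        df = validate_phenotypes(pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(20)],
            "group": ["patient"] * 10 + ["control"] * 10,
            "age": rng.uniform(18, 40, 20),
            "sex": list("MF") * 10,
            "tiv": rng.uniform(1e6, 1.4e6, 20),
        }))
        d = DesignMatrix.from_phenotypes(df)
        E = freedman_lane_residuals(rng.standard_normal((20, 5)), d)
        Z = d.reduced_design()
        proj = Z.T @ E / np.linalg.norm(Z, axis=0)[:, None]
        assert np.allclose(proj, 0, atol=1e-8)


class TestSmoothing:
    def _vol(self, data, voxel=3.0):
        return GMVolume("s", data, np.diag([voxel] * 3 + [1.0]))

    def test_fwhm_zero_is_identity(self, rng):
        v = self._vol(rng.random((10, 10, 10)))
        out = vbm.smooth_volume(v, 0.0)
        assert np.array_equal(out.data, v.data)

    def test_delta_spike_spread_matches_sigma(self):
        """FWHM 6 mm on 3 mm voxels: the smoothed spike has spatial SD
        6 / (2 sqrt(2 ln 2)) = 2.548 mm per axis."""
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        out = vbm.smooth_volume(self._vol(data), 6.0)
        x = (np.arange(21) - 10) * 3.0
        for axis in range(3):
            marg = out.data.sum(axis=tuple(i for i in range(3) if i != axis))
            sd = np.sqrt(np.sum(marg * x ** 2) / marg.sum())
            assert sd == pytest.approx(6.0 / 2.3548, rel=0.01)

    def test_mass_preserved_for_interior_signal(self, rng):
        data = np.zeros((24, 24, 24))
        data[8:16, 8:16, 8:16] = rng.random((8, 8, 8))
        out = vbm.smooth_volume(self._vol(data), 6.0)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-6)

    def test_constant_region_invariant_in_interior(self):
        out = vbm.smooth_volume(self._vol(np.ones((30, 30, 30))), 6.0)
        assert np.allclose(out.data[10:20, 10:20, 10:20], 1.0, atol=1e-9)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            vbm.smooth_volume(self._vol(np.ones((5, 5, 5))), -1.0)


class TestSmoothness:
    def test_recovers_known_fwhm(self, rng):
        """Gaussian noise smoothed at 6 mm: estimate within +-15%."""
        sigma_vox = 6.0 / 2.3548 / 3.0
        res = np.stack([ndimage.gaussian_filter(
            rng.standard_normal((32, 32, 32)), sigma_vox) for _ in range(40)])
        mask = np.zeros((32, 32, 32), bool)
        mask[4:-4, 4:-4, 4:-4] = True
        est = vbm.estimate_smoothness(res[:, mask], mask,
                                      np.array([3.0, 3.0, 3.0]))
        assert np.all(np.abs(est.fwhm_mm - 6.0) < 0.9)

    def test_white_noise_fwhm_near_voxel_size(self, rng):
        res = rng.standard_normal((20, 16, 16, 16))
        mask = np.ones((16, 16, 16), bool)
        est = vbm.estimate_smoothness(res[:, mask], mask,
                                      np.array([3.0, 3.0, 3.0]))
        # unsmoothed noise: FWHM on the scale of one voxel (about 3-5 mm)
        assert np.all(est.fwhm_mm < 6.0)

    def test_search_volume_proportional_to_mask(self, rng):
        res = np.stack([ndimage.gaussian_filter(
            rng.standard_normal((24, 24, 24)), 1.0) for _ in range(15)])
        m1 = np.zeros((24, 24, 24), bool)
        m1[2:12] = True
        m2 = np.zeros((24, 24, 24), bool)
        m2[2:22] = True
        e1 = vbm.estimate_smoothness(res[:, m1], m1, np.array([3.0] * 3))
        e2 = vbm.estimate_smoothness(res[:, m2], m2, np.array([3.0] * 3))
        ratio = e2.search_volume_resels / e1.search_volume_resels
        expected = m2.sum() / m1.sum()
        # same field, so resels per voxel agree closely; volume scales
        assert ratio == pytest.approx(expected, rel=0.1)

    def test_too_few_residuals_rejected(self, rng):
        mask = np.ones((8, 8, 8), bool)
        with pytest.raises(ValueError, match="10"):
            vbm.estimate_smoothness(rng.standard_normal((5, 512)), mask,
                                    np.array([3.0] * 3))


class TestClusterInference:
    def test_empty_suprathreshold_set(self, regional_run):
        stat = regional_run["stat"]
        flat = vbm.StatMap(t=np.zeros_like(stat.t), df=stat.df,
                           mask=stat.mask, affine=stat.affine)
        table = vbm.rft_cluster_inference(flat, regional_run["smooth_est"])
        assert len(table) == 0

    def test_min_extent_rule_removes_small_clusters(self, regional_run):
        """Raising the extent threshold above the recovered cluster's size
        removes it regardless of its p-value."""
        table = regional_run["table"]
        assert len(table) > 0
        biggest = int(table["cluster_size_voxels"].max())
        filtered = vbm.rft_cluster_inference(
            regional_run["stat"], regional_run["smooth_est"],
            min_extent=biggest)
        assert len(filtered) == 0

    def test_extent_monotone_in_height_threshold(self, regional_run):
        """A stricter voxel threshold never enlarges any cluster."""
        sizes = []
        for voxel_p in (0.01, 0.001, 0.0001):
            t = vbm.rft_cluster_inference(
                regional_run["stat"], regional_run["smooth_est"],
                voxel_p=voxel_p, cluster_p=0.999999, min_extent=0)
            sizes.append(t["cluster_size_voxels"].max() if len(t) else 0)
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_permutation_inference_deterministic(self, regional_run):
        kw = dict(mask=regional_run["mask"], min_extent=20, n_perm=100,
                  seed=7)
        a = vbm.permutation_cluster_inference(regional_run["smoothed"],
                                              regional_run["design"], **kw)
        b = vbm.permutation_cluster_inference(regional_run["smoothed"],
                                              regional_run["design"], **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_rft_and_permutation_agree_on_planted_cluster(self, regional_run):
        """Both correction routes recover the same planted cluster."""
        rft = regional_run["table"]
        perm = vbm.permutation_cluster_inference(
            regional_run["smoothed"], regional_run["design"],
            mask=regional_run["mask"], min_extent=20, n_perm=200, seed=3)
        assert len(rft) == 1 and len(perm) == 1
        assert rft.loc[0, "tail"] == perm.loc[0, "tail"] == "pos"
        assert rft.loc[0, "cluster_size_voxels"] == \
            perm.loc[0, "cluster_size_voxels"]

    def test_peak_reported_in_world_mm(self, regional_run):
        row = regional_run["table"].iloc[0]
        affine = regional_run["stat"].affine
        shape = regional_run["stat"].t.shape
        lo = affine[:3, 3]
        hi = lo + np.diag(affine)[:3] * (np.array(shape) - 1)
        peak = np.array([row.peak_x_mm, row.peak_y_mm, row.peak_z_mm])
        assert np.all(peak >= lo) and np.all(peak <= hi)
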