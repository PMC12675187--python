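"""Shared fixtures: small synthetic cohorts generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from neuroscn import simulate, vbm
from neuroscn.glm import DesignMatrix


TINY = dict(grid_shape=(20, 24, 20), n_roi=12, n_patients=10, n_controls=10)


@pytest.fixture(scope="session")
def tiny_cohort():
    """10+10 subjects, 12 regions on a 20x24x20 grid — fast unit-test cohort."""
    return simulate.generate_cohort(simulate.null_preset(seed=11, **TINY))


@pytest.fixture(scope="session")
def desk_cohort():
    """The default desk-scale null cohort: 30+30, 90 regions, 32x38x32."""
    return simulate.generate_cohort(simulate.null_preset(seed=21))


@pytest.fixture(scope="session")
def regional_run():
    """Regional-effect cohort with the full smoothed VBM pipeline applied."""
    cfg = simulate.regional_preset(seed=31)
    cohort = simulate.generate_cohort(cfg)
    smoothed = [vbm.smooth_volume(v, 6.0) for v in cohort.volumes]
    design = DesignMatrix.from_phenotypes(cohort.phenotypes)
    mask = vbm.make_analysis_mask(smoothed)
    stat, resid = vbm.fit_voxelwise_glm(smoothed, design, mask,
                                        return_residuals=True)
    smooth_est = vbm.estimate_smoothness(resid, mask,
                                         smoothed[0].voxel_size_mm)
    table, labels = vbm.rft_cluster_inference(stat, smooth_est, min_extent=20,
                                              return_label_map=True)
    return dict(cfg=cfg, cohort=cohort, smoothed=smoothed, design=design,
                mask=mask, stat=stat, smooth_est=smooth_est, table=table,
                labels=labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
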