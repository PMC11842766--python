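import numpy as np
import pytest

from foodnet import simulate


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def default_space():
    """Default 36-item food space at a fixed seed (shared, read-only)."""
    cfg = simulate.SyntheticConfig(seed=7)
    return simulate.gen_food_space(cfg, cfg.rng())


@pytest.fixture(scope="session")
def small_cohort():
    """Small subject x ROI cohort for fast clustering/RSA tests."""
    cfg = simulate.SyntheticConfig(
        seed=3, n_subjects=6, n_items=12, voxels_per_roi=60,
        n_rois_net1=3, n_rois_net2=4, n_outlier_rois=1,
    )
    rng = cfg.rng()
    space = simulate.gen_food_space(cfg, rng)
    return cfg, space, simulate.gen_roi_patterns(cfg, space, rng)
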