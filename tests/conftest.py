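import warnings

import numpy as np
import pytest

from neurofuse import phantom, volumes

warnings.filterwarnings("ignore", message="zero-variance")


@pytest.fixture(scope="session")
def small_cohort():
    """40 subjects on a coarse 16^3 grid: fast, exercises every code path."""
    cfg = phantom.PhantomConfig(
        n_subjects=40, grid_shape=(16, 16, 16), voxel_volume=64.0,
        lesion_axis_range=(1.0, 3.0), seed=7)
    return phantom.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_batch(small_cohort):
    return volumes.stack_volumes(small_cohort.volumes)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
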