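import numpy as np
import pytest

from saccdecode.atlas import GridSpec, ROI_LABELS, build_atlas
from saccdecode.design import DesignParams, make_experiment_design


@pytest.fixture(scope="session")
def default_params():
    return DesignParams()


@pytest.fixture(scope="session")
def one_run(default_params):
    """A deterministic default-design run (36 blocks)."""
    return make_experiment_design(default_params, seed=123, n_runs=1).runs[0]


@pytest.fixture(scope="session")
def tiny_atlas():
    """Full eight-ROI atlas with 40-voxel masks (fast)."""
    return build_atlas(sizes={label: 40 for label in ROI_LABELS}, seed=0)


@pytest.fixture(scope="session")
def default_atlas():
    """The paper-sized atlas (564 SEF ... 1043 parietal); built once."""
    return build_atlas(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
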