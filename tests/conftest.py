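import numpy as np
import pytest

from linescan.config import PipelineConfig
from linescan.synth import SessionDesign, make_phantom_1d


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced-FOV phantom used throughout the suite (64 mm, 164 voxels)."""
    return make_phantom_1d(fov_mm=64.0, voxel_mm=0.39)


@pytest.fixture
def small_config():
    return PipelineConfig(fov_mm=64.0, n_coils=4, seed=0, noise_sd=0.02)


@pytest.fixture
def short_design():
    """Two-trial design for fast forward-model tests."""
    return SessionDesign(n_trials=2, n_coils=4, noise_sd=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
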