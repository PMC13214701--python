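import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octseg.features import extract_blocks
from octseg.parametric import compute_maps
from octseg.simulate import TissueModel, simulate_training_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tissue():
    return TissueModel()


@pytest.fixture(scope="session")
def training_blocks(tissue):
    """Feature blocks of the 23-scan homogeneous training cohort (460 blocks)."""
    blocks = []
    for scan, meta in simulate_training_cohort(seed=7):
        maps = compute_maps(scan, noise_reference=tissue.noise_level)
        blocks.extend(extract_blocks(maps, labels=meta.label))
    return blocks


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
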