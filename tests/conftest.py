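import numpy as np
import pytest

from wardsim.economics import CostParameters, EffectEstimates
from wardsim.synthetic_hospital import GeneratorConfig, generate_hospital


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def costs():
    return CostParameters()


@pytest.fixture
def effects():
    return EffectEstimates()


@pytest.fixture(scope="session")
def ten_unit_hospital():
    """A small synthetic hospital (10 units, 2 specialty groups)."""
    cfg = GeneratorConfig(n_hospitals=1, units_per_hospital=10, groups_per_hospital=2)
    return generate_hospital(cfg, seed=7)
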