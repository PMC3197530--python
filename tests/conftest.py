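import numpy as np
import pytest

from melimm import AffinityParams, InteractionParams, ScenarioConfig
from melimm.lattice import HexLattice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def affinity():
    return AffinityParams()


@pytest.fixture
def inter():
    return InteractionParams()


@pytest.fixture
def small_lattice():
    return HexLattice(12)


def tiny_config(**kw) -> ScenarioConfig:
    """A fast, reduced-scale scenario for engine-level tests."""
    defaults = dict(lattice_L=60, duration_days=10, seed=7)
    defaults.update(kw)
    return ScenarioConfig(**defaults)
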