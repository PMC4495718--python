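import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from mtmesh import FiberSpec, generate_fiber
from mtmesh.synthetic import CONTROL_REGIME, OE_REGIME


@pytest.fixture(scope="session")
def control_fiber():
    """A seeded control-like synthetic fiber (56.1 nm spacing, 10% deviants)."""
    return generate_fiber(CONTROL_REGIME.with_seed(42), fiber_id="ctrl")


@pytest.fixture(scope="session")
def oe_fiber():
    """A seeded OE-like synthetic fiber (48.1 nm spacing, 40% deviants)."""
    return generate_fiber(OE_REGIME.with_seed(42), fiber_id="oe")


@pytest.fixture(scope="session")
def small_fiber():
    """A tiny 6-MT fiber for fast rendering/segmentation tests."""
    spec = FiberSpec(n_mts=6, connectors_per_mt=0.5, rng_seed=3)
    return generate_fiber(spec, fiber_id="small")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
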