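import numpy as np
import pytest

from diracsense.gating import GatingParams
from diracsense.simulate import ScenarioConfig


@pytest.fixture(scope="session")
def device_params() -> GatingParams:
    """The fitted parameter set of the reference device: CNP at +335 mV,
    areal gate capacitance 5.26 × 10⁻² F m⁻² (total 1.72 µF)."""
    return GatingParams(v_cnp=0.335, areal_capacitance=5.26e-2)


@pytest.fixture(scope="session")
def scenario() -> ScenarioConfig:
    return ScenarioConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250121)
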