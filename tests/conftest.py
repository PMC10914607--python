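import numpy as np
import pytest

from syntroph import build_scenario
from syntroph.simulate import SimulationConfig


@pytest.fixture()
def pair():
    """Nominal two-member mutualistic co-culture."""
    return build_scenario("pair_twoway_symmetric")


@pytest.fixture()
def mono():
    """Nominal single-strain producer."""
    return build_scenario("mono_producer")


@pytest.fixture()
def prototroph():
    """Single strain, no leak, no death: textbook Monod batch growth."""
    return build_scenario("mono_producer", phi={"y1": 0.0}, params={"eta": 0.0})


@pytest.fixture()
def fast_cfg():
    """Coarse, cheap solver settings for sweeps and GSA-scale runs."""
    return SimulationConfig(dt_out=1.0, rtol=1e-6, atol=1e-9)


@pytest.fixture()
def tight_cfg():
    """Default tight tolerances for invariant checks."""
    return SimulationConfig()
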