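import numpy as np
import pytest

from memsyn.device import DeviceParams, init_device
from memsyn.protocols import prepare_device


@pytest.fixture(scope="session")
def params() -> DeviceParams:
    return DeviceParams()


@pytest.fixture(scope="session")
def fresh_low(params):
    """Device at the low initial conductance used in the reference experiments."""
    return init_device(0.1, params)


@pytest.fixture(scope="session")
def prepared_devices(params):
    """Devices activated to the three experienced-conductance levels.

    Preparation is deterministic, so one snapshot per level is shared across
    tests; tests must copy before stimulating.
    """
    return {g0: prepare_device(g0, params) for g0 in (0.5, 3.0, 7.0)}
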