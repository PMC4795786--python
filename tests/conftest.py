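import numpy as np
import pytest

from nocgmp import default_scenario, simulate


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def control_result(scenario):
    """Control-condition trajectory on the standard 0-200 s, 1-s grid."""
    return simulate(scenario.params, scenario.control)


@pytest.fixture(scope="session")
def stressed_result(scenario):
    """500 μM H2O2 trajectory on the standard grid."""
    return simulate(scenario.params, scenario.stressed)
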