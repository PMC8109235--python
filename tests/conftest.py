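import numpy as np
import pytest

import refloat as rf


@pytest.fixture(scope="session")
def qgrid():
    """Coarse Q grid for fast model evaluations in tests."""
    return rf.default_qgrid(60)


@pytest.fixture(scope="session")
def popc_initial():
    return rf.measured_fixture("POPC", "CaCl2_initial")


@pytest.fixture(scope="session")
def popc_initial_data(popc_initial, qgrid):
    """Three simulated contrasts of the POPC / initial-CaCl2 scenario."""
    return rf.simulate_condition(popc_initial, grid=qgrid, seed=11)
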