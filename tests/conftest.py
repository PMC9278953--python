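import numpy as np
import pytest

from pvnet import SquarePulseProtocol, make_pv_cell, run_fi_curve


@pytest.fixture(scope="session")
def pv_cell():
    return make_pv_cell()


@pytest.fixture(scope="session")
def fi_protocol():
    return SquarePulseProtocol()


@pytest.fixture(scope="session")
def control_fi(pv_cell, fi_protocol):
    """Control F-I table of the calibrated PV model, shared across tests."""
    return run_fi_curve(pv_cell, fi_protocol)


@pytest.fixture(scope="session")
def voltage_grid():
    return np.arange(-100.0, 60.0, 2.5)
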