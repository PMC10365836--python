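import numpy as np
import pytest

from mcdkit import device, solve_flow
from mcdkit.gradient import StratificationSpec, solve_stratified
from mcdkit.swimmers import imaging_schedule


@pytest.fixture(scope="session")
def mcd_flow():
    """Designed and forward-solved reference device network."""
    return device.solve_mcd()


@pytest.fixture(scope="session")
def mcd_constraints():
    return device.mcd_constraints()


@pytest.fixture(scope="session")
def default_schedule():
    """Six channels, 75 cycles over 10 minutes."""
    return imaging_schedule(6, 75, 600.0)


@pytest.fixture(scope="session")
def stock_field(default_schedule):
    """Evolved gradient at the stock concentration (Ci = C0)."""
    times = np.union1d(np.arange(0.0, 602.0, 2.0), [default_schedule.max()])
    return solve_stratified(StratificationSpec(), times, ny=256)
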