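import numpy as np
import pytest

from sprayroom import (EmissionEvent, FlowParameters, build_grid,
                       solve_matrix_exponential)


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture
def chamber():
    """The room-chamber flow parameters: V = 30 m^3, lambda = 1.0 h^-1."""
    return FlowParameters(volume=30.0, air_change_rate=1.0, lambda_ex=4.64)


@pytest.fixture
def source_release():
    """Instantaneous 795 mg release into the source compartment at t = 0."""
    return EmissionEvent(source="111", mass=795.0, start_time=0.0)


@pytest.fixture
def exact_trace(grid, chamber, source_release):
    """Noise-free eight-compartment trajectories on a 20-min grid."""
    times = np.linspace(0.0, 1.0 / 3.0, 601)
    return solve_matrix_exponential(grid, chamber, source_release, times)
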