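import numpy as np
import pytest

from kaiabc import ModelParameters, simulate


@pytest.fixture(scope="session")
def small_params():
    """Small ensemble at paper concentrations (V scaled with N)."""
    return ModelParameters.standard(N=80)


@pytest.fixture(scope="session")
def std_traj():
    """A moderately long standard-condition trajectory, shared across tests."""
    p = ModelParameters.standard(N=150)
    return p, simulate(p, duration=140.0, warmup=60.0, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
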