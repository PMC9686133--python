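import numpy as np
import pytest

from lipidfilm import synthetic


@pytest.fixture
def dppc_truth():
    """DPPC-like ground truth (NN tilt) with the default 2% map noise."""
    return synthetic.GroundTruth(lattice=synthetic.dppc_lattice(), seed=1)


@pytest.fixture
def sm_truth():
    return synthetic.GroundTruth(seed=7)


@pytest.fixture
def gixd_grids():
    return np.linspace(1.0, 1.75, 400), np.linspace(0.0, 0.8, 160)


@pytest.fixture
def step_potentials():
    # reaches −1.1 V so film and bare charge curves have merged at the join
    return np.round(np.arange(0.4, -1.12, -0.05), 3)
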