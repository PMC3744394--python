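import dataclasses

import numpy as np
import pytest

from betaox.config import default_parameters
from betaox.fixtures import make_toy_parameter_set
from betaox.network import build_network
from betaox.steadystate import solve_steady_state


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def network():
    return build_network()


@pytest.fixture(scope="session")
def toy():
    """Reduced C4/C6 model: (network, params) solvable in well under a second."""
    spec, p, variant = make_toy_parameter_set()
    return build_network(spec, variant), p


@pytest.fixture(scope="session")
def steady_25(network, params):
    """Reference steady state of the standard model at 25 uM palmitoyl-CoA."""
    return solve_steady_state(network, params)


@pytest.fixture()
def with_substrate(params):
    def make(value: float):
        return dataclasses.replace(
            params, boundaries={**params.boundaries, "palmitoylCoA_e": float(value)}
        )

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130815)
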