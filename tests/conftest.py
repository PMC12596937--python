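import numpy as np
import pytest

from ivtkit.scenarios import make_scenarios
from ivtkit.speciation import EquilibriumConstantSet


@pytest.fixture(scope="session")
def constants():
    return EquilibriumConstantSet.default()


@pytest.fixture(scope="session")
def bundle():
    return make_scenarios(seed=0)


@pytest.fixture(scope="session")
def sims(bundle):
    """Simulated trajectories of every bundled scenario, shared suite-wide."""
    return {name: bundle.simulate(name) for name in bundle.policies}


@pytest.fixture(scope="session")
def seq(bundle):
    return bundle.seq
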