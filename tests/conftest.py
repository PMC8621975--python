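import numpy as np
import pytest

from modelbalance import MetabolicNetwork, build_schema
from modelbalance.synthetic_data import chain_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniuni():
    """A <=> B with both metabolites clamped (1 reaction, 2 metabolites)."""
    return chain_network(1)


@pytest.fixture
def chain3():
    """Linear 3-reaction chain with external ends."""
    return chain_network(3)


@pytest.fixture
def triangle():
    """Closed cycle A -> B -> C -> A, all internal."""
    S = np.array([[-1, 0, 1], [1, -1, 0], [0, 1, -1]])
    return MetabolicNetwork(["A", "B", "C"], ["R1", "R2", "R3"], S, np.ones(3, bool))


@pytest.fixture
def uniuni_schema(uniuni):
    return build_schema(uniuni)


def random_feasible_point(network, schema, rng, v=None):
    """A (q_basic, x, v) triple with sign-consistent forces: draw q and x,
    then set fluxes along the force signs."""
    from modelbalance import driving_forces, expand_constants

    q = rng.normal(0, 1, schema.n_basic)
    x = rng.normal(np.log(0.1), 0.8, network.n_metabolites)
    constants = expand_constants(schema, q)
    theta = driving_forces(constants.ln_keq, network.S, x)
    if v is None:
        v = np.sign(theta) * np.abs(rng.normal(1.0, 0.3, network.n_reactions))
    return q, x, v
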