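import numpy as np
import pytest
from hypothesis import settings

from yieldopt import YieldSpec, fixtures

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def unit(i, n=11):
    e = np.zeros(n)
    e[i] = 1.0
    return e


@pytest.fixture(scope="session")
def network():
    return fixtures.example_network()


@pytest.fixture(scope="session")
def scenarios():
    """{sid: (model, polyhedron)} for the six example scenarios."""
    return {sid: fixtures.scenario(sid) for sid in fixtures.SCENARIO_IDS}


@pytest.fixture(scope="session")
def biomass_yield(network):
    """Y_B/S = r4 / r1."""
    n = network.n_reactions
    return YieldSpec.single_ratio(n, network.reaction_index("R4"),
                                  network.reaction_index("R1"))


@pytest.fixture(scope="session")
def product_yield(network):
    """Y_P/S = r3 / r1."""
    n = network.n_reactions
    return YieldSpec.single_ratio(n, network.reaction_index("R3"),
                                  network.reaction_index("R1"))


def random_feasible_points(gen, rng, count):
    """Random feasible points of a polyhedron from its generator set:
    convex weights on bounded generators plus conical weights on the
    unbounded ones (bounded conical coefficients keep points finite)."""
    bounded = [g.x for g in gen.bounded]
    unbounded = [g.x for g in gen.unbounded]
    n = gen.polyhedron.n
    out = []
    for _ in range(count):
        x = np.zeros(n)
        if bounded:
            w = rng.dirichlet(np.ones(len(bounded)))
            x = x + np.array(bounded).T @ w
        if unbounded:
            w = rng.exponential(1.0, size=len(unbounded))
            x = x + np.array(unbounded).T @ w
        out.append(x)
    return out
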