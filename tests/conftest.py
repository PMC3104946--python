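import numpy as np
import pytest

from hilladair import (
    AdairRates,
    build_common_state_map,
    enumerate_adair_space,
    enumerate_hill_space,
)

# the copy numbers used throughout the reference parameterizations
P0, L0 = 2, 5


@pytest.fixture(scope="session")
def h2_spaces():
    hill = enumerate_hill_space(2, P0, L0)
    adair = enumerate_adair_space(2, P0, L0)
    return hill, adair, build_common_state_map(hill, adair)


@pytest.fixture(scope="session")
def weak_coop_rates():
    """All unit rates: weakly cooperative, intermediates long-lived."""
    return AdairRates((1.0, 1.0), (1.0, 1.0))


@pytest.fixture(scope="session")
def strong_coop_rates():
    """K1=10, K2=0.1: strongly cooperative, intermediates short-lived."""
    return AdairRates((1.0, 10.0), (10.0, 1.0))


def brute_force_hill_states(h, p0, l0):
    """Oracle: all (n0, nh, nA) satisfying the conservation laws."""
    states = set()
    for n0 in range(p0 + 1):
        for nh in range(p0 + 1):
            for nA in range(l0 + 1):
                if n0 + nh == p0 and nA + h * nh == l0:
                    states.add((n0, nh, nA))
    return states


def brute_force_adair_states(h, p0, l0):
    """Oracle: all (n0..nh, nA) satisfying the conservation laws."""
    import itertools

    states = set()
    for occ in itertools.product(range(p0 + 1), repeat=h + 1):
        if sum(occ) != p0:
            continue
        for nA in range(l0 + 1):
            if nA + sum(j * nj for j, nj in enumerate(occ)) == l0:
                states.add(occ + (nA,))
    return states


def dirichlet_on(rng, n):
    """A random strictly valid probability vector of length n."""
    return rng.dirichlet(np.ones(n))
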