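"""Shared fixtures.

Session-scoped network builds are shared across tests (quenched networks;
only inputs/protocols vary), keeping the suite's runtime dominated by the
physics that actually needs simulating.
"""

import numpy as np
import pytest

from seqspeed import (
    PlasticityRule,
    StandardParams,
    generate_patterns,
    homogeneous_network,
    nonlinear_two_pop_network,
    two_pop_network,
)


@pytest.fixture(scope="session")
def small_patterns():
    return generate_patterns(P=3, N=20, seed=11)


@pytest.fixture(scope="session")
def bilinear_rule():
    return PlasticityRule.bilinear()


@pytest.fixture(scope="session")
def standard_two_pop():
    """Standard two-population bilinear network (N=8000, c=0.05)."""
    return two_pop_network(seed=0)


@pytest.fixture(scope="session")
def standard_two_pop_small():
    """Half-size two-population network (N=4000 at the same mean
    in-degree of 400) with coarse dt=1 ms integration, used for
    trial-based learning where thousands of retrieval simulations are
    needed."""
    params = StandardParams(N=4000, c=0.1, dt=1.0)
    return two_pop_network(seed=0, params=params)


@pytest.fixture(scope="session")
def nonlinear_fixture():
    """Threshold-rule two-population network (A=20, sigma=0.05)."""
    return nonlinear_two_pop_network(seed=0)


@pytest.fixture(scope="session")
def homogeneous_half():
    """Homogeneous z=0.5 network at standard scale."""
    return homogeneous_network(0.5, seed=0)
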