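"""Shared fixtures: networks and simulations reused across the suite.

Expensive artifacts (10 s simulations, the downscaled multi-area network) are
session-scoped so that unit and acceptance tests share one realization.
"""

import numpy as np
import pytest

from mam import meanfield
from mam.fixtures import make_balanced_ei, make_small_multiarea, make_toy_bistable
from mam.simulator import draw_synapses, simulate


@pytest.fixture(scope="session")
def toy_spec():
    return make_toy_bistable(seed=0)


@pytest.fixture(scope="session")
def balanced_spec():
    return make_balanced_ei(seed=0)


@pytest.fixture(scope="session")
def balanced_run(balanced_spec):
    """10 s simulation of the monostable balanced E-I network."""
    return simulate(balanced_spec, duration=10_000.0, seed=9)


@pytest.fixture(scope="session")
def multiarea_spec():
    return make_small_multiarea(n_areas=4, seed=7)


@pytest.fixture(scope="session")
def multiarea_synapses(multiarea_spec):
    return draw_synapses(multiarea_spec, seed=11)


@pytest.fixture(scope="session")
def multiarea_run(multiarea_spec, multiarea_synapses):
    """10 s simulation of the 4-area downscaled network."""
    return simulate(multiarea_spec, multiarea_synapses, duration=10_000.0, seed=11)


@pytest.fixture(scope="session")
def multiarea_la_rates(multiarea_spec):
    reports = meanfield.find_fixed_points(
        multiarea_spec,
        np.zeros((1, len(multiarea_spec.grid))),
        tol=1e-9,
        compute_stability=False,
    )
    assert reports[0].converged
    return reports[0].rates
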