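"""Shared fixtures: toy models, simulated time points, cheap refinement configs.

Expensive artifacts (simulated reflection sets, refined mixtures) are
session-scoped so the suite pays for them once.
"""

import numpy as np
import pytest

from kokflash.mixture import RefinementConfig, refine_primary
from kokflash.simulate import (
    OX_LABEL,
    ScenarioConfig,
    default_restraints,
    make_oec_toy,
    simulate_timepoint,
)


@pytest.fixture(scope="session")
def toy_s3():
    return make_oec_toy("S3_like")


@pytest.fixture(scope="session")
def toy_s0():
    return make_oec_toy("S0_like")


@pytest.fixture(scope="session")
def scenario_config():
    return ScenarioConfig()


@pytest.fixture(scope="session")
def sim_1200(scenario_config):
    """Noisy (3%) three-component time point at 1,200 us: the 0.40/0.35/0.25 split."""
    return simulate_timepoint(1200.0, scenario_config)


@pytest.fixture(scope="session")
def sim_1200_noiseless():
    return simulate_timepoint(1200.0, ScenarioConfig(noise=0.0))


@pytest.fixture(scope="session")
def restraints_guess(sim_1200):
    _, guess, _ = sim_1200
    return default_restraints(guess.primary.model)


@pytest.fixture(scope="session")
def light_config():
    """Cheap refinement settings for tests that only need qualitative fits."""
    return RefinementConfig(max_cycles=30, tol=1e-8)


@pytest.fixture(scope="session")
def refined_1200(sim_1200, restraints_guess):
    """Standard refinement of the noisy 1,200-us point with the true Ox occupancy."""
    fobs, guess, truth = sim_1200
    g = guess.copy()
    g.primary.model.atom(OX_LABEL).occupancy = truth.ox_occupancy
    return refine_primary(g, fobs, restraints_guess)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
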