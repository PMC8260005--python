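"""Shared fixtures: environments, solver settings, and a cached pool."""

import numpy as np
import pytest

from crossfeed import EnvironmentParams, fixture
from crossfeed.cell_dynamics import SolverConfig
from crossfeed.community_dynamics import CommunityConfig
from crossfeed.networks import generate_species_pool


@pytest.fixture(scope="session")
def fig2_env():
    """The two-species example's environment (unit volume ratio and
    degradation, nutrient reservoir at 1 supplied at rate 10)."""
    return EnvironmentParams(S_env=1.0, V_env=1.0, R_deg=1.0, D_S_env=10.0)


@pytest.fixture(scope="session")
def paper_env():
    """Random-network study conditions: dilute nutrient, crowded cells,
    very slow environmental degradation."""
    return EnvironmentParams(S_env=0.03, V_env=3.0, R_deg=5e-5, D_S_env=20.0)


@pytest.fixture(scope="session")
def solver():
    """Workstation-scale solver policy (shorter time cap)."""
    return SolverConfig(t_cap=2e4)


@pytest.fixture(scope="session")
def community_config(solver):
    return CommunityConfig(solver=solver)


@pytest.fixture(scope="session")
def leaker():
    return fixture("fig2_leaker")


@pytest.fixture(scope="session")
def consumer():
    return fixture("fig2_consumer")


@pytest.fixture(scope="session")
def small_pool(paper_env, solver):
    """A cached constraint-satisfying pool of n=10 random species."""
    return generate_species_pool(n=10, rho=2, n_enzyme=2, N=5, env=paper_env,
                                 rng_seed=3, solver_config=solver)
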