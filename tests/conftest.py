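"""Shared fixtures: mid-range kinetic parameters and reusable simulations."""

import numpy as np
import pytest

from senspread import ligand_mc
from senspread.params import KineticParams, derive_compound_params


@pytest.fixture(scope="session")
def params() -> KineticParams:
    """Mid-range parameter set: Table-1-central kinetics."""
    return KineticParams()


@pytest.fixture(scope="session")
def derived(params):
    return derive_compound_params(params)


@pytest.fixture(scope="session")
def mc_geometry(params):
    """Random (RSA) monolayer tile reused across Monte-Carlo tests."""
    return ligand_mc.place_cells(
        params.sigma, params.rcell, 100 * params.rcell, mode="random", seed=1,
        h=1.2,
    )


@pytest.fixture(scope="session")
def mc_outcomes(mc_geometry, params, derived):
    """One medium-sized trajectory batch shared by the ligand-capture tests."""
    t_max = 12.0 * mc_geometry.h / (derived.nu * derived.keff)
    return ligand_mc.simulate_trajectories(
        mc_geometry, params, derived, n=6000, t_max=t_max, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
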