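"""Shared fixtures: small fast demographies, default grids and models.

Unit tests run on a deliberately tiny two-epoch demography (a few hundred
generations, a few hundred diploids) so that whole-trajectory simulations
cost milliseconds; the acceptance tests use the rescaled European model.
"""

import numpy as np
import pytest
from hypothesis import settings

from strsel.evo_model import (
    AlleleGrid,
    DemographicModel,
    Epoch,
    MutationModel,
    european_demography,
)


settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_demog():
    """Tiny demography for fast unit tests: 300 generations at 400 diploids
    then 50 generations of growth."""
    return DemographicModel((Epoch(300, 400.0), Epoch(50, 400.0, 0.01)))


@pytest.fixture(scope="session")
def eur_demog():
    return european_demography()


@pytest.fixture(scope="session")
def dinuc_grid():
    return AlleleGrid(xopt=11, repeat_unit_len=2)


@pytest.fixture(scope="session")
def trinuc_grid():
    return AlleleGrid(xopt=5, repeat_unit_len=3)


@pytest.fixture(scope="session")
def dinuc_mut():
    return MutationModel(mu0=1e-4, L=0.05, rho=0.9, beta=0.3)


@pytest.fixture(scope="session")
def hot_mut():
    """High-rate model so short trajectories accumulate variation."""
    return MutationModel(mu0=1e-3, L=0.05, rho=0.9, beta=0.3)
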