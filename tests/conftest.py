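"""Shared fixtures: the expensive Monte-Carlo cells are session-scoped.

Every full-size cell (2000 replicates, n = 500, prevalence 0.5) is
computed once and shared between the property tests and the reproduction
tests.
"""

import numpy as np
import pytest

from nestedroc import SimulationConfig, run_cell

SEED = 1234
REPLICATES = 2000
MU_GRID = (0.0, 0.1, 0.2, 0.3)
RHO_GRID = (0.0, 0.1, 0.3, 0.5)


def base_config(mu=0.0, mu_star=0.0, rho=0.0, n=500, prevalence=0.5, seed=SEED):
    return SimulationConfig(
        n=n, prevalence=prevalence, mu=mu, mu_star=mu_star, rho=rho, seed=seed
    )


def full_cell(mu=0.0, mu_star=0.0, rho=0.0, **kwargs):
    return run_cell(base_config(mu=mu, mu_star=mu_star, rho=rho, **kwargs),
                    REPLICATES, alpha=0.05, keep_pvalues=True)


@pytest.fixture(scope="session")
def cell_null():
    """Fully null cell: mu = mu_star = rho = 0."""
    return full_cell()


@pytest.fixture(scope="session")
def null_grid(cell_null):
    """All 16 null configurations (mu_star = 0) keyed by (mu, rho)."""
    cells = {(0.0, 0.0): cell_null}
    for mu in MU_GRID:
        for rho in RHO_GRID:
            if (mu, rho) not in cells:
                cells[(mu, rho)] = full_cell(mu=mu, rho=rho)
    return cells


@pytest.fixture(scope="session")
def cell_power_01():
    return full_cell(mu_star=0.1)


@pytest.fixture(scope="session")
def cell_power_02():
    return full_cell(mu_star=0.2)


@pytest.fixture(scope="session")
def cell_power_03():
    return full_cell(mu_star=0.3)


@pytest.fixture(scope="session")
def cell_power_03_rho05():
    return full_cell(mu_star=0.3, rho=0.5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


def mc_tolerance(r_hat: float, r_ref: float, replicates: int = REPLICATES) -> float:
    """Two-run Monte-Carlo comparison band: 3 SE for each estimate."""
    se = lambda r: np.sqrt(r * (1.0 - r) / replicates)
    return 3.0 * se(r_hat) + 3.0 * se(r_ref)
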