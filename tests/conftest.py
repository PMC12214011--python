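import numpy as np
import pytest

import immunores as ir


@pytest.fixture(scope="session")
def base_params():
    """Canonical kinetics at the reference treatment point of the 1D runs."""
    return ir.table1_nondim(alpha=0.07, sigma_u=0.014, sigma_w=0.5)


@pytest.fixture(scope="session")
def turing_params(base_params):
    """A point inside the Turing-unstable band (sigma_u sweep, sigma_w=0.5)."""
    return base_params.replace(sigma_u=0.018)


@pytest.fixture(scope="session")
def dom30():
    return ir.DomainND.interval(30.0, 256)


def random_valid_params(rng: np.random.Generator) -> ir.NondimParams:
    """Random draw within the published nondimensional ranges."""
    return ir.NondimParams(
        alpha=rng.uniform(0.0, 0.154),
        mu_u=0.167,
        rho_u=0.692,
        sigma_u=rng.uniform(0.0, 0.05),
        gamma_v=0.1,
        delta_u=rng.uniform(0.747, 8264.0),
        mu_w=55.56,
        rho_w=2.5,
        sigma_w=rng.uniform(0.0, 20.0),
        gamma_w=1e-3,
        delta_w=rng.uniform(1.067, 8264.0),
    )


def random_valid_state(rng: np.random.Generator):
    return (rng.uniform(0.0, 2.0), rng.uniform(0.0, 1.2), rng.uniform(0.0, 2.0))
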