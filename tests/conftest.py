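import numpy as np
import pytest

from ipmcor import ModelSpec, VitalRateParams, mesh_from_params

#: case-study-scale fixed effects (the calibration means) with the fixed
#: residual variances; the reference parameter set for most tests
SHEEP_KWARGS = dict(
    beta_s0=-4.25, beta_sm=1.92,
    beta_b0=-1.47, beta_bm=0.50,
    beta_g0=1.20, beta_gm=0.63,
    beta_h0=0.46, beta_hm=0.57,
    sigma2_g=0.09**2, sigma2_h=0.2**2,
)


@pytest.fixture(scope="session")
def sheep_params() -> VitalRateParams:
    return VitalRateParams(**SHEEP_KWARGS)


@pytest.fixture(scope="session")
def temporal_params(sheep_params) -> VitalRateParams:
    return sheep_params.replace(nu2_b=0.45**2, nu2_g=0.03**2)


@pytest.fixture(scope="session")
def individual_params(sheep_params) -> VitalRateParams:
    return sheep_params.replace(theta2_b=0.45**2, theta2_g=0.03**2)


@pytest.fixture(scope="session")
def mesh80(sheep_params):
    return mesh_from_params(sheep_params, n_points=80)


@pytest.fixture(scope="session")
def mesh40(sheep_params):
    return mesh_from_params(sheep_params, n_points=40)


@pytest.fixture(scope="session")
def i1() -> ModelSpec:
    return ModelSpec("I1")


@pytest.fixture(scope="session")
def small_panel(sheep_params):
    """A small I1 panel reused by io/inference tests."""
    from ipmcor import simulate_population

    return simulate_population(
        ModelSpec("I1"), sheep_params, n0=120, T=10, seed=42, missing_rate_r=0.1
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
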