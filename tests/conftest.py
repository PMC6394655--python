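import numpy as np
import pytest

import biodose as bd


@pytest.fixture(scope="session")
def silene_curve():
    return bd.load_curve("silene")


@pytest.fixture(scope="session")
def clor_curve():
    return bd.load_curve("clor_bm")


@pytest.fixture(scope="session")
def silene_sample():
    return bd.AberrationSample(u=85, w=28)


@pytest.fixture(scope="session")
def clor_sample():
    return bd.AberrationSample(u=35, w=500)


@pytest.fixture(scope="session")
def silene_prior():
    """Scaled-Gaussian ratio prior used with the SILENE criticality sample."""
    return bd.ScaledGaussianPrior(rho_hat=0.64, sigma_rho=0.25)


@pytest.fixture(scope="session")
def clor_prior():
    """Gaussian gamma-fraction prior used with the CLOR reactor sample."""
    return bd.GaussianPrior(theta_hat=0.92, sigma_theta=0.02)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def random_feasible_case(rng, w=1000):
    """A random curve / ratio / true gamma dose with an exactly consistent count."""
    curve = bd.CalibrationCurve(
        y0=rng.uniform(0, 0.005),
        alpha=rng.uniform(0.05, 1.5),
        beta=rng.uniform(0.001, 0.2),
        gamma_coef=rng.uniform(0.0, 0.2),
    )
    rho = rng.uniform(0.0, 5.0)
    d_gamma = rng.uniform(0.05, 6.0)
    yf = bd.yield_mixed(rho * d_gamma, d_gamma, curve)
    u = int(round(yf * w))
    if u < 1:
        return None
    return bd.AberrationSample(u=u, w=w), rho, d_gamma, curve
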