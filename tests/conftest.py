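import numpy as np
import pytest

from pairsis import EpidemicParams, SpatialMoments


@pytest.fixture
def params():
    """Reference rates: beta_G = beta_L = 10, alpha = 1, theta = 1/4."""
    return EpidemicParams(beta_G=10.0, beta_L=10.0, alpha=1.0)


@pytest.fixture
def moments_mid():
    """Moderately clustered mosaic: x_C = 0.5, p_CC = 0.3 (clustering 1.2)."""
    return SpatialMoments(x_C=0.5, p_CC=0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_admissible(rng, endemic_for=None):
    """Random admissible (strain G, params, moments) draw.

    With ``endemic_for='global'`` the draw is conditioned on the
    completely global strain being endemic (beta_G x_C > alpha).
    """
    from pairsis import Strain

    while True:
        x_C = rng.uniform(0.15, 0.9)
        p_CC = rng.uniform(0.02, 1.0) * x_C
        beta_G = rng.uniform(0.5, 20.0)
        beta_L = rng.uniform(0.5, 20.0)
        alpha = rng.uniform(0.1, 8.0)
        G = rng.uniform(0.0, 1.0)
        if endemic_for == "global" and beta_G * x_C <= alpha * 1.05:
            continue
        return (
            Strain(G),
            EpidemicParams(beta_G, beta_L, alpha),
            SpatialMoments(x_C, p_CC),
        )
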