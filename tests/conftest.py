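import numpy as np
import pytest

from cellmove.core import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fig2_params():
    """High-density small-square parameter set (directional bias only)."""

    def make(beta=0.1, **overrides):
        kwargs = dict(m=10.0, alpha=0.0, sigma_w=0.5, beta=beta, sigma_v=0.5,
                      lambda_mu=5.0, sigma_mu=0.05, Lx=20.0, Ly=20.0, n=200)
        kwargs.update(overrides)
        return ModelParams(**kwargs)

    return make


@pytest.fixture
def fig4_params():
    """Fibroblast-scale strip-domain parameter set."""

    def make(**overrides):
        kwargs = dict(m=5.0, alpha=0.0, sigma_w=10.0, beta=1000.0, sigma_v=10.0,
                      lambda_mu=0.1, sigma_mu=2.5, Lx=4500.0, Ly=450.0, n=286)
        kwargs.update(overrides)
        return ModelParams(**kwargs)

    return make
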