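import numpy as np
import pytest

from pgbar.model import ModelParameters, kinetics_to_ar
from pgbar.priors import (
    GammaPrior,
    InverseGammaPrior,
    PriorSpec,
    TruncatedNormalPrior,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def theta():
    """Moderate-rate parameter set at 50 Hz sampling."""
    return ModelParameters(
        r0=2.0,
        r1=25.0,
        w01=5.0,
        w10=8.0,
        a_max=1.0,
        tau_r=0.02,
        tau_d=0.1,
        c0=0.2,
        sigma2=0.25,
        sigma2_b=0.3,
    )


@pytest.fixture
def dt():
    return 0.02


@pytest.fixture
def coeffs(theta, dt):
    return kinetics_to_ar(theta.tau_r, theta.tau_d, theta.a_max, dt)


@pytest.fixture
def fast_theta():
    """GCaMP8f-like kinetics for 3 kHz traces."""
    return ModelParameters(
        r0=0.1,
        r1=100.0,
        w01=1.0,
        w10=100.0,
        a_max=1.0,
        tau_r=0.0037,
        tau_d=0.040,
        c0=0.0,
        sigma2=(1.0 / 3.4) ** 2,
        sigma2_b=0.01,
    )


@pytest.fixture
def tight_priors():
    """Well-behaved priors for sampler-correctness diagnostics."""
    return PriorSpec(
        r0=GammaPrior(2, 2),
        r1=GammaPrior(2, 0.2),
        w01=GammaPrior(2, 2),
        w10=GammaPrior(2, 0.5),
        a_max=TruncatedNormalPrior(1.0, 0.3, 0.0),
        tau_r=TruncatedNormalPrior(0.02, 0.005, 0.002),
        tau_d=TruncatedNormalPrior(0.1, 0.02, 0.01),
        c0=TruncatedNormalPrior(0.0, 0.2, 0.0),
        sigma2=InverseGammaPrior(10, 0.9),
        sigma2_b=InverseGammaPrior(10, 0.9),
    )
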