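import numpy as np
import pytest

from trainsig import ModelKind, ModelParameters, ProtocolConfig, generate_subject
from trainsig.datasets import MEDIAN_TI_PARAMS


@pytest.fixture(scope="session")
def median_ti_params() -> ModelParameters:
    """Median inhibition-model parameter estimates across the six subjects."""
    return MEDIAN_TI_PARAMS


@pytest.fixture(scope="session")
def full_params() -> ModelParameters:
    """A full six-parameter set valid for every model kind."""
    return ModelParameters(
        k_off=0.0305, k_s1=0.292, k_s2=0.0074, k_i=0.0021, k_f1=0.1, k_f2=0.1
    )


@pytest.fixture(scope="session")
def noisefree_ti_series(median_ti_params):
    """A noise-free synthetic subject generated under Model TI."""
    cfg = ProtocolConfig(noise_sd=0.0, seed=101)
    return generate_subject(ModelKind.TI, median_ti_params, cfg)


@pytest.fixture(scope="session")
def noisy_ti_series(median_ti_params):
    """A synthetic TI subject with 3 W measurement noise."""
    cfg = ProtocolConfig(noise_sd=3.0, seed=202)
    return generate_subject(ModelKind.TI, median_ti_params, cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
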