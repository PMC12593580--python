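import numpy as np
import pytest

from epicalib import DiseaseConfig, SVEIRParams, TownConfig, predicted_incidence


@pytest.fixture(scope="session")
def small_town_config() -> TownConfig:
    """A ~500-agent town, big enough for multi-generation outbreaks."""
    return TownConfig().scaled(500 / 9547)


@pytest.fixture(scope="session")
def disease_default() -> DiseaseConfig:
    return DiseaseConfig()


@pytest.fixture(scope="session")
def sveir_base() -> SVEIRParams:
    """The study's generating parameters: beta 1.5/d, gamma 1/8 d."""
    return SVEIRParams(beta=1.5, gamma=0.125, sigma=0.1, ve=0.97, vr=0.5, N=9547)


@pytest.fixture(scope="session")
def noiseless_incidence(sveir_base) -> np.ndarray:
    return predicted_incidence(sveir_base, horizon_days=120)
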