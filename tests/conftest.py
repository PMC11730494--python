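import numpy as np
import pytest

from fampri.linkstats import DiseaseModel
from fampri.simfam import simulate_family, study_emulation_preset


@pytest.fixture(scope="session")
def dominant_model() -> DiseaseModel:
    """The default disease model: 1% prevalence, 0.90 penetrance for carriers."""
    return DiseaseModel(prevalence=0.01, penetrances=(0.0, 0.9, 0.9))


@pytest.fixture(scope="session")
def preset_sim():
    """One study-emulation dataset, shared across tests (read-only)."""
    return simulate_family(study_emulation_preset(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240317)
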