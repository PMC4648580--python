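import pytest

from cescore.model_config import default_model
from cescore.synthetic_data import (
    GeneratorConfig,
    generate_ce_exposure,
    generate_reference_countries,
    generate_scored_countries,
)
from cescore.threshold_derivation import derive_all


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def reference(gen_config):
    return generate_reference_countries(gen_config)


@pytest.fixture(scope="session")
def exposure_reference(gen_config):
    return generate_ce_exposure(gen_config)


@pytest.fixture(scope="session")
def scored_countries(gen_config):
    return generate_scored_countries(gen_config)


@pytest.fixture(scope="session")
def thresholds(model, reference, exposure_reference):
    return derive_all(model, reference, exposure_reference)
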