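import pytest

from oksmap.response_mapping import load_published_model
from oksmap.synthetic import PRESETS, generate_cohort
from oksmap.tariff import load_tariff


@pytest.fixture(scope="session")
def uk():
    return load_tariff()


@pytest.fixture(scope="session")
def published_model():
    return load_published_model()


@pytest.fixture(scope="session")
def mixed_cohort():
    """Small clustered pre/post cohort with EQ-5D from the published model."""
    return generate_cohort(PRESETS("mixed", n_patients=400), seed=123)
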