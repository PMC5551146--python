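import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from boiledegg import classify_table, load_measured_fa, load_model, load_oxon_pairs


@pytest.fixture(scope="session")
def model():
    return load_model()


@pytest.fixture(scope="session")
def oxon_table():
    return load_oxon_pairs()


@pytest.fixture(scope="session")
def oxon_predictions(oxon_table, model):
    return classify_table(oxon_table, model)


@pytest.fixture(scope="session")
def measured_fixture():
    return load_measured_fa()


@pytest.fixture(scope="session")
def measured_predictions(measured_fixture, model):
    table, _ = measured_fixture
    return classify_table(table, model)
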