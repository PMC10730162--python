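import pytest

from ibdevo import synthetic_data as sd


@pytest.fixture(scope="session")
def default_config():
    return sd.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def cohort(default_config):
    return sd.generate_cohort(default_config)


@pytest.fixture(scope="session")
def mutation_tables(default_config, cohort):
    return sd.generate_mutation_tables(default_config, cohort)


@pytest.fixture(scope="session", params=sd.TOY_MODEL_NAMES)
def toy_model(request):
    return sd.generate_toy_model(request.param)
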