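import pytest

from audsim import build_parameter_set, load_config, scenarios_from_config


@pytest.fixture(scope="session")
def default_config():
    return load_config(None)


@pytest.fixture(scope="session")
def params(default_config):
    return build_parameter_set(default_config)


@pytest.fixture(scope="session")
def scenarios(default_config):
    return scenarios_from_config(default_config)


@pytest.fixture(scope="session")
def baseline(scenarios):
    return next(s for s in scenarios if s.baseline)
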