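import pytest

from carecascade import run_cascade, table1_fixture


@pytest.fixture(scope="session")
def fixture_config():
    return table1_fixture()


@pytest.fixture(scope="session")
def baseline(fixture_config):
    return fixture_config.baseline


@pytest.fixture(scope="session")
def baseline_result(baseline):
    return run_cascade(baseline)


@pytest.fixture
def config_yaml(fixture_config, tmp_path):
    from carecascade import save_config

    path = tmp_path / "config.yaml"
    save_config(fixture_config, path)
    return path
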