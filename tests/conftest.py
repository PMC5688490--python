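import pytest

from costkit.fixtures import FixtureConfig, generate_country_fixture
from costkit.io import load_scenario

from helpers import make_mini_scenario


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The seed-42 toy-country file set, generated once per session."""
    out = tmp_path_factory.mktemp("toy_country")
    generate_country_fixture(FixtureConfig(seed=42), out)
    return out


@pytest.fixture(scope="session")
def toy_scenario(fixture_dir):
    return load_scenario(fixture_dir / "scenario.json")


@pytest.fixture
def mini_scenario():
    return make_mini_scenario()
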