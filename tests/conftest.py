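import pytest

from lexiclean.engine import RuleConfig, default_resources
from lexiclean.fixtures import FixtureSpec, generate_lexicon, golden_fixture


@pytest.fixture(scope="session")
def resources():
    return default_resources()


@pytest.fixture(scope="session")
def golden():
    return golden_fixture()


@pytest.fixture()
def small_fixture():
    return generate_lexicon(FixtureSpec(seed=11))


@pytest.fixture()
def recommended():
    return RuleConfig.from_profile("recommended")


@pytest.fixture()
def full_profile():
    return RuleConfig.from_profile("full")
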