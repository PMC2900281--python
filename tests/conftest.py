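import pytest
from hypothesis import settings

from forestmeta import (
    MetaInput,
    expected_tables,
    generate_ipd,
    hypothetical_fixture,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_config():
    return hypothetical_fixture()


@pytest.fixture(scope="session")
def fixture_tables(fixture_config):
    return expected_tables(fixture_config)


@pytest.fixture(scope="session")
def fixture_meta(fixture_config, fixture_tables):
    return MetaInput.from_tables(
        fixture_tables, "log-rr", fixture_config.subgroup_props
    )


@pytest.fixture(scope="session")
def fixture_ipd(fixture_config):
    return generate_ipd(fixture_config)
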