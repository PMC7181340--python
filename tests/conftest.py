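import pytest

from antioxkit.fixtures import FIXTURE_REFERENCES, petunidin_fixture
from antioxkit.mechanisms import site_table
from antioxkit.species import Phase


@pytest.fixture(scope="session")
def petunidin():
    return petunidin_fixture()


@pytest.fixture(scope="session")
def fixture_refs():
    return FIXTURE_REFERENCES


@pytest.fixture(scope="session")
def gas_site_table(petunidin, fixture_refs):
    return site_table(petunidin.species_for(Phase.GAS), fixture_refs, phase=Phase.GAS)


@pytest.fixture(scope="session")
def water_site_table(petunidin, fixture_refs):
    return site_table(petunidin.species_for(Phase.WATER), fixture_refs, phase=Phase.WATER)
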