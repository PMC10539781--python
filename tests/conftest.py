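import pytest
from hypothesis import settings

from cidnp_kit.species import load_tml_fixture, species_by_name

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def tml():
    """Packaged TML fixture: (species-by-name dict, observations list)."""
    species, observations = load_tml_fixture()
    return species_by_name(species), observations


@pytest.fixture(scope="session")
def tml_species(tml):
    return tml[0]


@pytest.fixture(scope="session")
def tml_observations(tml):
    return tml[1]


@pytest.fixture
def ox_observations(tml_observations):
    return [o for o in tml_observations if o.species_name == "TML-"]


@pytest.fixture
def red_observations(tml_observations):
    return [o for o in tml_observations if o.species_name == "TMLH"]
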