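import pytest

from efmflux import enumerate_efms
from efmflux.synthetic_data import (
    bacterial_network,
    chain_network,
    diamond_network,
    plant_core_network,
)


@pytest.fixture(scope="session")
def chain():
    return chain_network()


@pytest.fixture(scope="session")
def diamond():
    return diamond_network()


@pytest.fixture(scope="session")
def plant():
    return plant_core_network()


@pytest.fixture(scope="session")
def plant_modes(plant):
    return enumerate_efms(plant, label="plant_all")


@pytest.fixture(scope="session")
def bacterial_modes():
    return {s: enumerate_efms(bacterial_network(s), label=s)
            for s in ("glucose", "fructose", "sucrose")}


MINIMAL_DOC = """\
-ENZREV

-ENZIRREV
R1

-METINT

-METEXT
A B

-CAT
R1 : A = B .
"""


@pytest.fixture
def minimal_doc():
    return MINIMAL_DOC
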