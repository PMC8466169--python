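import pytest

from dssm import VarietyGenotype, variety
from dssm.genetics import enumerate_female_genotypes


@pytest.fixture
def picholine():
    return variety("Picholine")


@pytest.fixture
def cayon():
    return variety("Cayon")


@pytest.fixture
def tanche():
    return variety("Tanche")


@pytest.fixture(scope="session")
def all_genotypes():
    """All 40 admissible joint genotypes (2 groups x 20 R pairs)."""
    return [
        VarietyGenotype(name=f"{g}-{''.join(pair)}", dsi_group=g, pasi=pair)
        for g in ("G1", "G2")
        for pair in enumerate_female_genotypes()
    ]
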