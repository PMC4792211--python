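import pytest

from aminolipid.lipids import LipidSpecies, parse_acyl
from aminolipid.simulate import noiseless_model, qtof_model, qtrap_model


@pytest.fixture
def lysyl_pg_32():
    return LipidSpecies("PG", parse_acyl("32:0"), "Lys")


@pytest.fixture
def lysyl_pg_30():
    return LipidSpecies("PG", parse_acyl("30:0"), "Lys")


@pytest.fixture
def alanyl_pg_32():
    return LipidSpecies("PG", parse_acyl("32:0"), "Ala")


@pytest.fixture
def pg_32():
    return LipidSpecies("PG", parse_acyl("32:0"))


@pytest.fixture
def lysyl_pe_30():
    return LipidSpecies("PE", parse_acyl("30:0"), "Lys")


@pytest.fixture
def exact_model():
    return noiseless_model(seed=1)


@pytest.fixture
def qtrap():
    return qtrap_model(seed=1)


@pytest.fixture
def qtof():
    return qtof_model(seed=1)
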