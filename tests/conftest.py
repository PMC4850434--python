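import pytest

from mmtsa import GeneticModel, load_table1, study_effects


@pytest.fixture(scope="session")
def table1():
    """The packaged nine-study MTHFR C677T / multiple myeloma dataset."""
    return load_table1()


@pytest.fixture(scope="session")
def allele_effects(table1):
    return study_effects(table1, GeneticModel.ALLELE)


@pytest.fixture(scope="session")
def recessive_effects(table1):
    return study_effects(table1, GeneticModel.RECESSIVE)
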