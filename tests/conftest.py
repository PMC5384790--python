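import pytest

from minisplice import fixtures
from minisplice.simulate import SyntheticGeneSpec, make_synthetic_minigene


@pytest.fixture(scope="session")
def mgbr2():
    """The BRCA2 exons 14-20 reporter construct fixture."""
    return fixtures.load_construct()


@pytest.fixture(scope="session")
def catalog(mgbr2):
    """Every characterised cohort species as a Transcript."""
    return fixtures.transcript_catalog(mgbr2)


@pytest.fixture(scope="session")
def primers(mgbr2):
    return {p.name: p for p in mgbr2.primers}


@pytest.fixture(scope="session")
def synthetic_gene():
    """A small sequence-bearing reporter with a translatable CDS."""
    return make_synthetic_minigene(SyntheticGeneSpec(n_exons=3, seed=7))
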