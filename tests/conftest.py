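import pytest

from petype import synth
from petype.align import SubstitutionMatrix


@pytest.fixture(scope="session")
def refset():
    """The seeded archetype reference set shared across tests."""
    return synth.make_reference_set(seed=1)


@pytest.fixture(scope="session")
def blosum():
    return SubstitutionMatrix.blosum62()
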