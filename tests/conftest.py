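import pytest

from sqgsuite import pairalign, syndata
from sqgsuite.syndata import FamilySpec


@pytest.fixture(scope="session")
def family20():
    """A 20-member family at 80% target identity, length 200."""
    return syndata.make_family(
        FamilySpec(n_members=20, target_intra_identity=80.0, length=200,
                   seed=5, prefix="fam")
    )


@pytest.fixture(scope="session")
def decoys200(family20):
    """200 shuffled-composition decoys derived from the family."""
    return syndata.make_decoys(family20, 200, seed=9)


@pytest.fixture(scope="session")
def two_families():
    famA = syndata.make_family(
        FamilySpec(8, 80.0, 200, seed=1, prefix="A", taxonomy="taxon1")
    )
    famB = syndata.make_family(
        FamilySpec(8, 80.0, 200, seed=2, prefix="B", taxonomy="taxon2")
    )
    return famA, famB


@pytest.fixture(scope="session")
def two_family_edges(two_families):
    famA, famB = two_families
    return pairalign.all_vs_all(famA + famB, mode="local")
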