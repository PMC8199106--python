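import numpy as np
import pytest

from rhizomics import (
    ProteinRecord,
    TaxonomyEntry,
    blosum62,
    generate_reference_db,
)


@pytest.fixture(scope="session")
def matrix():
    return blosum62()


@pytest.fixture(scope="session")
def small_db():
    """Seeded 3-group reference database (Bacteria/Archaea/Eukaryota)."""
    records, taxonomy = generate_reference_db(
        groups=("Bacteria", "Archaea", "Eukaryota"),
        sequences_per_group=4,
        length_range=(80, 120),
        seed=11,
    )
    return records, taxonomy


@pytest.fixture
def mini_taxonomy():
    return {
        "t_bac": TaxonomyEntry("t_bac", "Rickettsia", "Bacteria", ("cellular", "Bacteria")),
        "t_bac2": TaxonomyEntry("t_bac2", "Schaalia", "Bacteria", ("cellular", "Bacteria")),
        "t_arc": TaxonomyEntry("t_arc", "Methanobrevibacter", "Archaea", ("cellular", "Archaea")),
        "t_euk": TaxonomyEntry("t_euk", "Ostreococcus", "Eukaryota", ("cellular", "Eukaryota")),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


@pytest.fixture
def make_protein(rng):
    counter = iter(range(10**6))

    def _make(length=100, id=None):
        return ProteinRecord(id=id or f"p{next(counter)}", sequence=random_protein(rng, length))

    return _make
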