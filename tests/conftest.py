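import numpy as np
import pytest

from darkbench import fixtures as fx
from darkbench.taxonomy import parse_taxonomy_dump

# Hand-written minimal dump: root, one phylum, E. coli with a synonym.
TINY_NAMES = (
    "1\t|\troot\t|\t\t|\tscientific name\t|\n"
    "2\t|\tProteobacteria\t|\t\t|\tscientific name\t|\n"
    "3\t|\tEscherichia coli\t|\t\t|\tscientific name\t|\n"
    "3\t|\tBacterium coli\t|\t\t|\tsynonym\t|\n"
)
TINY_NODES = (
    "1\t|\t1\t|\tno rank\t|\n"
    "2\t|\t1\t|\tphylum\t|\n"
    "3\t|\t2\t|\tspecies\t|\n"
)


@pytest.fixture(scope="session")
def tiny_taxonomy():
    return parse_taxonomy_dump(TINY_NAMES, TINY_NODES)


@pytest.fixture(scope="session")
def fixture_spec():
    return fx.FixtureSpec(
        n_phyla=3,
        families_per_phylum=3,
        genera_per_family=3,
        species_per_genus=4,
        synonym_rate=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def taxonomy(fixture_spec):
    return fx.fixture_taxonomy(fixture_spec)


@pytest.fixture(scope="session")
def catalog(taxonomy, fixture_spec):
    cat, _ = fx.make_catalog_and_sequences(taxonomy, fixture_spec)
    return cat


@pytest.fixture(scope="session")
def big_catalog():
    """Catalog large enough for every grid design (600 known + 600 unknown)."""
    spec = fx.FixtureSpec(
        n_phyla=5,
        families_per_phylum=5,
        genera_per_family=6,
        species_per_genus=10,
        status_mix=(0.45, 0.15, 0.4),
        seed=23,
    )
    tax = fx.fixture_taxonomy(spec)
    cat, _ = fx.make_catalog_and_sequences(tax, spec)
    return cat


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
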