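import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from foramflow.refdb import ReferenceEntry, TaxonPath
from foramflow.synthetic_data import TaxonomySpec, refdb_entries, simulate_refdb


@pytest.fixture(scope="session")
def demo_refdb():
    """One simulated reference database shared across read-only tests."""
    records, taxonomy = simulate_refdb(TaxonomySpec(), seed=11)
    return records, taxonomy


@pytest.fixture(scope="session")
def demo_entries(demo_refdb):
    records, taxonomy = demo_refdb
    return refdb_entries(records, taxonomy)


def make_path(phylum="Foraminifera", class_="Tubothalamea", order="Miliolida",
              family="Soritidae", genus="Amphisorus", species="Amphisorus hemprichii"):
    return TaxonPath(phylum, class_, order, family, genus, species)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
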