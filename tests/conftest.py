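import pandas as pd
import pytest

from bulktrap import make_community, make_genomes, make_taxonomy


class TableReport:
    """Minimal report stand-in: fixed distinct-minimiser counts per taxon.

    Filtering and comparison operations only need the
    ``distinct_minimisers_by_rank`` accessor, so tests can hand them exact
    counts without running the classifier.
    """

    def __init__(self, genus_counts=None, species_counts=None):
        self._by_rank = {
            "genus": pd.Series(genus_counts or {}, dtype=int).sort_index(),
            "species": pd.Series(species_counts or {}, dtype=int).sort_index(),
        }

    def distinct_minimisers_by_rank(self, rank):
        return self._by_rank[rank]


@pytest.fixture
def table_report_cls():
    return TableReport


@pytest.fixture(scope="session")
def toy_tree():
    return make_taxonomy(3, 2)


@pytest.fixture(scope="session")
def toy_genomes(toy_tree):
    return make_genomes(toy_tree, length=400, divergence=0.05, seed=11)


@pytest.fixture(scope="session")
def toy_community(toy_tree):
    return make_community(
        toy_tree, n_samples=3, seed=5, spike_species=("g3s1", "g3s2"), spike_reads=40
    )
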