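"""Shared fixtures: a small seeded reference database and read sets."""

import pytest

from planktag import io as pio
from planktag import lca, simulate


@pytest.fixture(scope="session")
def small_db():
    """3 families x 2 genera x 2 species, ~500 nt, default divergences."""
    return simulate.generate_reference_db(3, 2, 2, seed=7)


@pytest.fixture(scope="session")
def lineages(small_db):
    return lca.parse_lineage_table(simulate.lineage_table(small_db))


@pytest.fixture(scope="session")
def scheme():
    return simulate.default_tag_scheme(["A", "B"], seed=1)


@pytest.fixture(scope="session")
def clean_reads(small_db, scheme):
    """Error-free full-length reads from a 6-taxon community, demultiplexed."""
    comm = simulate.generate_community(small_db, 6, seed=3, sample_id="A")
    reads, truth = simulate.generate_reads(
        comm, small_db, scheme, 80, error_rate=0.0,
        length_model=simulate.LengthModel(full_fraction=1.0),
        seed=5,
    )
    by_sample, unassigned = pio.demultiplex(
        [pio.RawRead(*r) for r in reads], scheme
    )
    assert not unassigned
    return by_sample["A"].reads, truth
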