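import numpy as np
import pytest

from splicecomb.event_catalog import build_catalog
from splicecomb.formats_io import Gene, GeneModelSet, Transcript
from splicecomb.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """One small synthetic study shared by read-only tests."""
    return simulate_study(SimConfig(seed=7))


@pytest.fixture()
def cassette_gene():
    """Three-exon gene with the middle exon skipped in one isoform."""
    exons = [(100, 200), (300, 400), (500, 600)]
    return Gene("gA", "chrI", "+", [
        Transcript("gA.t1", list(exons)),
        Transcript("gA.t2", [exons[0], exons[2]]),
    ])


@pytest.fixture()
def cassette_event(cassette_gene):
    events = build_catalog(GeneModelSet([cassette_gene]))
    assert len(events) == 1
    return events[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
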