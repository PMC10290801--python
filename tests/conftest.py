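import pytest

from pksmine import simulate


@pytest.fixture(scope="session")
def fixture_data():
    """The deterministic validation fixture (genes, records, anchors)."""
    return simulate.paper_fixture()


@pytest.fixture(scope="session")
def sim_run():
    """One default simulated experiment: (genes, truth, count matrix)."""
    config = simulate.SimConfig(seed=1)
    genes, _, truth = simulate.generate_genome(config, with_sequence=False)
    cm = simulate.generate_counts(config, truth)
    return genes, truth, cm
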