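import pytest

from hybridase import synth


@pytest.fixture(scope="session")
def fx():
    """The deterministic study fixture (haplotype trio + variant truth)."""
    return synth.make_paper_fixture()


@pytest.fixture(scope="session")
def study_truth():
    """Simulation truth at the study conditions."""
    return synth.paper_truth(seed=0)
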