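import pytest

from seqlot.experiment_design import bundled_roster


@pytest.fixture(scope="session")
def roster():
    """Full 10-sequence roster (deviant-detection modality)."""
    return bundled_roster()


@pytest.fixture(scope="session")
def meg_roster():
    """7-sequence passive-listening roster."""
    return bundled_roster("meg")


@pytest.fixture(scope="session")
def roster_by_name(roster):
    return {r.name: r for r in roster}
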