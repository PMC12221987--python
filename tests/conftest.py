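import pytest

from persisterkit.mechanistic import load_default_params, simulate_lineage
from persisterkit.singlecell import detect_entrances


@pytest.fixture(scope="session")
def wt_params():
    return load_default_params()


@pytest.fixture(scope="session")
def wt_lineage(wt_params):
    """A moderate wild-type lineage run shared across single-cell tests."""
    return simulate_lineage(wt_params, 15_000, seed=42)


@pytest.fixture(scope="session")
def wt_traces(wt_lineage):
    return wt_lineage.to_traces()


@pytest.fixture(scope="session")
def wt_events(wt_traces):
    return detect_entrances(wt_traces)
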