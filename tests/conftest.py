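import pytest

from somaticsieve import FilterConfig, SvConfig
from somaticsieve import fixtures as fx


@pytest.fixture
def filter_config():
    """Default filter thresholds with empty interval masks."""
    return FilterConfig()


@pytest.fixture(scope="session")
def table1_records():
    """The 17 coding-mutation reference records."""
    return fx.coding_mutation_records()


@pytest.fixture(scope="session")
def cnv_reference_segments():
    """The 17 copy-number reference segments."""
    return fx.cnv_segments()


@pytest.fixture(scope="session")
def sv_fixture():
    """(raw candidate calls incl. distractors, centromere mask)."""
    return fx.sv_candidate_fixture()


@pytest.fixture
def sv_config(sv_fixture):
    _, centromeres = sv_fixture
    return SvConfig(centromere_intervals=centromeres)
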