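import pytest

from karyoclust import iscn


@pytest.fixture(scope="session")
def table1():
    """The four bundled cell-line composite records, keyed by line name."""
    return {r.source_label: r for r in iscn.table1_records()}


@pytest.fixture(scope="session")
def fixture_path():
    return iscn.table1_path()
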