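import pytest

from loopinv.hairpin import call_inversions, scan_alignment
from loopinv.synthetic import table2_fixture


@pytest.fixture(scope="session")
def fixture_alignment():
    msa, expectations = table2_fixture()
    return msa, expectations


@pytest.fixture(scope="session")
def fixture_events(fixture_alignment):
    msa, _ = fixture_alignment
    return call_inversions(msa, scan_alignment(msa))
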