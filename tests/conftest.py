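import pytest

from aphidkit import default_marker, packaged_reference_fragments


@pytest.fixture(scope="session")
def marker():
    return default_marker()


@pytest.fixture(scope="session")
def reference_fragments():
    return packaged_reference_fragments()
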