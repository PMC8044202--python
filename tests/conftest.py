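import pytest

from kip3slip import KIP3_TABLE1, Condition


@pytest.fixture(scope="session")
def kip3():
    """The Kip3 parameter preset used throughout."""
    return KIP3_TABLE1


@pytest.fixture(scope="session")
def unloaded_sat():
    """Unloaded operating point at saturating ATP."""
    return Condition.saturating(0.0)
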