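import pytest

from seqmetabias import JohnsonFixture, power_constant


@pytest.fixture(scope="session")
def c_standard():
    """The conventional power constant (two-sided 5% size, 80% power)."""
    return power_constant(0.05, 0.2)


@pytest.fixture(scope="session")
def johnson():
    return JohnsonFixture.load()
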