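import pytest

from lsbucket import BINARY, DNA


@pytest.fixture(scope="session")
def dna():
    return DNA


@pytest.fixture(scope="session")
def binary():
    return BINARY
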