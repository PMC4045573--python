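import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from keynodes import load_fixture

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def twogroup13():
    return load_fixture("twogroup13")


@pytest.fixture(scope="session")
def zachary():
    return load_fixture("zachary")


@pytest.fixture(scope="session")
def schematic32():
    return load_fixture("schematic32")
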