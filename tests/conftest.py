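import pytest

from fuzzygrn import load_pck1_fixture
from fuzzygrn.synth import make_table1_fixture


@pytest.fixture(scope="session")
def pck1():
    return load_pck1_fixture()


@pytest.fixture(scope="session")
def table1():
    return make_table1_fixture()
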