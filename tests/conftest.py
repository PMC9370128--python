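import pytest

from apricot_si.fixtures import load_fixture


@pytest.fixture(scope="session")
def panel():
    return load_fixture("panel")


@pytest.fixture(scope="session")
def registry():
    return load_fixture("registry")


@pytest.fixture(scope="session")
def table1():
    return load_fixture("compiled_si_table1")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("compiled_sc_table2")


@pytest.fixture(scope="session")
def study66():
    return load_fixture("study66")
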