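import pytest

import tubsig


@pytest.fixture(scope="session")
def scheme():
    return tubsig.default_scheme()


@pytest.fixture(scope="session")
def reference():
    return tubsig.load_reference()


@pytest.fixture(scope="session")
def table1():
    return tubsig.load_fixture_matrix("table1")


@pytest.fixture(scope="session")
def table2():
    return tubsig.load_fixture_matrix("table2")


@pytest.fixture(scope="session")
def table3():
    return tubsig.load_fixture_matrix("table3")
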