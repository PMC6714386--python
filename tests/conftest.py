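import pytest

from gcdesign import make_fixture


@pytest.fixture(scope="session")
def t1():
    return make_fixture("T1")


@pytest.fixture(scope="session")
def t2():
    return make_fixture("T2")


@pytest.fixture(scope="session")
def t3():
    return make_fixture("T3")


@pytest.fixture(scope="session")
def t1_model(t1):
    return t1[0]


@pytest.fixture(scope="session")
def t1_gt(t1):
    return t1[1]
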