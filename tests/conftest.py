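import pytest

from alsvarclass.fixtures import catalog_fixture, worked_examples_fixture, gene_kb_fixture
from alsvarclass.policy import PolicyConfig


@pytest.fixture(scope="session")
def kb():
    return gene_kb_fixture()


@pytest.fixture(scope="session")
def catalog():
    return catalog_fixture()


@pytest.fixture(scope="session")
def worked_examples():
    return worked_examples_fixture()


@pytest.fixture(scope="session")
def als_cfg():
    return PolicyConfig.preset("als")


@pytest.fixture(scope="session")
def baseline_cfg():
    return PolicyConfig.preset("baseline")
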