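import pytest

from ringcode import (
    default_params,
    expected_fate_map,
    load_default_composition,
    load_table1,
    wild_type_reference,
)


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def wt_reference(params):
    return wild_type_reference(params)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def fate_map():
    return expected_fate_map()


@pytest.fixture(scope="session")
def composition():
    return load_default_composition()
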