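import pytest

from reachcalc import FULL_PRECISION, REPLICATION, brazil_config


@pytest.fixture(scope="session")
def brazil():
    return brazil_config()


@pytest.fixture
def replication():
    return REPLICATION


@pytest.fixture
def full_precision():
    return FULL_PRECISION
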