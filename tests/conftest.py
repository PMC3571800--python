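import pytest

from qprobe.fixtures import generate_fixture
from qprobe.thermo import ThermoConfig


@pytest.fixture(scope="session")
def tcfg():
    return ThermoConfig()


@pytest.fixture(scope="session")
def t790m():
    """Point-mutation fixture (probe matches mutant, MBP primer set)."""
    return generate_fixture("EGFR_T790M", 7)


@pytest.fixture(scope="session")
def ex19del():
    """In-frame-deletion fixture (probe matches wild, WIP blocker)."""
    return generate_fixture("EGFR_ex19del", 7)


@pytest.fixture(scope="session")
def jak2():
    return generate_fixture("JAK2_V617F", 7)
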