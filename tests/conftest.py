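import pytest

from globlekin import GlobleParameters, fixture_parameter_sets


@pytest.fixture
def defaults() -> GlobleParameters:
    """A typical radiosensitive line: eps_i << eps_c, fast repair ~0.5 h."""
    return GlobleParameters(eps_i=0.005, eps_c=0.2, hlt_i=0.5)


@pytest.fixture(scope="session")
def all_fixture_sets() -> list[GlobleParameters]:
    """All published calibrations (17 dose-rate + 5 split-dose)."""
    return fixture_parameter_sets()
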