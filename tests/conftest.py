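import pytest

from camnet.network import Concentrations, ParameterSet


@pytest.fixture(scope="session")
def ref_params() -> ParameterSet:
    """Reference equilibrium constants (K9 = 0.078, K4 = 16.7, K2 = 1000)."""
    return ParameterSet.reference()


@pytest.fixture(scope="session")
def ref_conc() -> Concentrations:
    """Main-experiment totals: 0.713 uM CaM, 0.0237 uM reporter."""
    return Concentrations(cam_tot=0.713, mlck_tot=0.0237)
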