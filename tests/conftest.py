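import numpy as np
import pytest

from sludgeopt.asm2d import Asm2dParams, stoichiometric_matrix
from sludgeopt.influent import InfluentRecord
from sludgeopt.plant import PlantConfig, build_flowsheet, steady_state


@pytest.fixture(scope="session")
def params():
    return Asm2dParams()


@pytest.fixture(scope="session")
def stoich(params):
    return stoichiometric_matrix(params)


@pytest.fixture(scope="session")
def constant_record():
    return InfluentRecord(time=0.0, flow=35000.0, COD=260.0, TN=42.0, TP=9.0, NH4N=26.0, SS=180.0)


@pytest.fixture(scope="session")
def default_model():
    return build_flowsheet(PlantConfig())


@pytest.fixture(scope="session")
def baseline_steady(default_model, constant_record):
    """Steady plant state under the constant reference influent (shared:
    the spin-up is the expensive part of several downstream tests)."""
    return steady_state(default_model, constant_record)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
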