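import numpy as np
import pytest

from crnctrl.controller import ControllerConfig
from crnctrl.crn import CRN, compile_crn, steady_state
from crnctrl.plant import ProcessParams, inversion_constants


@pytest.fixture(scope="session")
def nominal_params() -> ProcessParams:
    return ProcessParams(kr1=0.005, kr2=1.6, kr3=0.0008, xT=5.5)


@pytest.fixture(scope="session")
def nominal_cfg() -> ControllerConfig:
    return ControllerConfig()


@pytest.fixture(scope="session")
def nominal_inv(nominal_params):
    return inversion_constants(nominal_params)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def settle(crn: CRN, inputs=None, x0=None, horizon=200.0, tol=1e-8, **kw):
    """Steady state of a compiled network under constant clamped inputs."""
    return steady_state(compile_crn(crn), x0=x0, inputs=inputs, horizon=horizon,
                        tol=tol, **kw)


@pytest.fixture(scope="session")
def settle_fn():
    return settle
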