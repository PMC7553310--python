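import numpy as np
import pytest

import isgdyn as isg
from isgdyn.reference import reference_parameters

TIME_GRID = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 8.0, 12.0, 24.0])


@pytest.fixture(scope="session")
def model_fb():
    return isg.build_model("core_feedback")


@pytest.fixture(scope="session")
def model_core():
    return isg.build_model("core")


@pytest.fixture(scope="session")
def ref_params_fb(model_fb):
    return reference_parameters(model_fb)


@pytest.fixture(scope="session")
def ref_params_core(model_core):
    return reference_parameters(model_core)


@pytest.fixture(scope="session")
def traj_fb(model_fb, ref_params_fb):
    """Reference trajectory at 500 U/ml on a fine grid (shared, read-only)."""
    times = np.linspace(0.0, 24.0, 97)
    return isg.simulate(model_fb, ref_params_fb, 500.0, times)
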