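import numpy as np
import pytest

import coxpet as cp


@pytest.fixture(scope="session")
def fine_times():
    return np.arange(0.0, 120.0001, 0.1)


@pytest.fixture(scope="session")
def input_params():
    return cp.InputModelParams()


@pytest.fixture(scope="session")
def input_function(input_params, fine_times):
    return cp.simulate_input(input_params, fine_times)


@pytest.fixture(scope="session")
def schedule_120():
    return cp.default_frame_schedule(120.0)


@pytest.fixture(scope="session")
def params_2t():
    """Reference reversible two-tissue parameters with analytic V_T = 2."""
    return cp.KineticParams(K1=0.1, k2=0.1, k3=0.05, k4=0.05)


@pytest.fixture(scope="session")
def small_scene_params():
    """A small, quick scene for image-pipeline unit tests."""
    return cp.SceneParams(shape=(256, 256), n_nuclei=35, n_autofluor=6, seed=11)


@pytest.fixture(scope="session")
def small_scene(small_scene_params):
    from coxpet.fish_synth import generate_scene

    return generate_scene(small_scene_params)
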