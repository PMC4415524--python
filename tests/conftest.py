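import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermoembryo import RecordingParams, gen_recording

settings.register_profile(
    "suite", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.filter_too_much])
settings.load_profile("suite")

SIGMOID_TRUTH = (30.0, 300.0, 4.0, 5.0)


@pytest.fixture(scope="session")
def noiseless_params() -> RecordingParams:
    return RecordingParams(sigmoid_truth=SIGMOID_TRUTH, noise_sd=0.0,
                           drift_step_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_recording(noiseless_params):
    return gen_recording(noiseless_params)


@pytest.fixture()
def exact_sine():
    t = np.arange(512.0)
    return t, 2.0 * np.sin(2.0 * np.pi * 0.0625 * t)
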