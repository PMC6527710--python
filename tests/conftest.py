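import numpy as np
import pytest

from megrwa.features import compute_model_rdms
from megrwa.synthetic import SyntheticStimulusSpec, generate_sensor_layout, generate_stimuli


@pytest.fixture(scope="session")
def stimulus_set():
    """The default synthetic stimulus set: 6 categories x 5, fixed seed."""
    return generate_stimuli(SyntheticStimulusSpec(seed=1))


@pytest.fixture(scope="session")
def model_rdms(stimulus_set):
    """Low-level, shape and category RDMs of the default stimulus set."""
    return compute_model_rdms(stimulus_set)


@pytest.fixture(scope="session")
def layout20():
    return generate_sensor_layout(20)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
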