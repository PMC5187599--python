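import numpy as np
import pytest

import gaitmode as gm
from gaitmode.ann import TrainConfig
from gaitmode.simulate import ScenarioConfig, generate_trial

FAST_TRAIN = TrainConfig(max_epochs=60, seed=11)


@pytest.fixture(scope="session")
def stair_cfg():
    return ScenarioConfig(scenario="stairs", seed=42)


@pytest.fixture(scope="session")
def ramp_cfg():
    return ScenarioConfig(scenario="ramp", seed=42)


@pytest.fixture(scope="session")
def noisefree_stair_cfg():
    return ScenarioConfig(scenario="stairs", seed=42,
                          noise_accel_sd=0.0, noise_pitch_sd=0.0)


@pytest.fixture(scope="session")
def stair_trial(stair_cfg):
    return generate_trial(stair_cfg, subject_id=1, trial_id=1)


@pytest.fixture(scope="session")
def noisefree_stair_trial(noisefree_stair_cfg):
    return generate_trial(noisefree_stair_cfg, subject_id=1, trial_id=1)


@pytest.fixture(scope="session")
def trained_recognizer(stair_trial):
    """One recognizer trained quickly on the default stairs training trial."""
    stream, truth = stair_trial
    rec, record = gm.train_recognizer(stream, truth.mode, truth.stance_windows,
                                      FAST_TRAIN)
    return rec, record


def world_az(stream):
    return gm.rotate_to_world(stream.quat, stream.accel_body)[:, 2]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
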