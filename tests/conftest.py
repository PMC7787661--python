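import numpy as np
import pytest

from reachopt.biomech import (ArmModel, ArmParams, MuscleParams, default_arm,
                              default_muscles)


@pytest.fixture
def arm() -> ArmParams:
    return default_arm()


@pytest.fixture
def muscle() -> MuscleParams:
    return MuscleParams("test_flexor", fmax=800.0, moment_arms=(0.0, 0.03))


@pytest.fixture
def muscle_model() -> ArmModel:
    return ArmModel(arm=default_arm(), muscles=default_muscles())


@pytest.fixture
def torque_model() -> ArmModel:
    return ArmModel(arm=default_arm(), muscles=[], mode="torque")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
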