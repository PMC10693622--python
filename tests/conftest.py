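import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from viscovent.actuator import (
    Actuator,
    ActuatorCalibration,
    ActuatorSettings,
    MagnetForceModel,
)
from viscovent.experiments import CALIBRATION_RUNS
from viscovent.ventilator import LungSettings, VentilatorSettings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def force_model() -> MagnetForceModel:
    return MagnetForceModel.for_pair("neodymium-4mm")


@pytest.fixture(scope="session")
def calibration() -> ActuatorCalibration:
    return ActuatorCalibration.default()


@pytest.fixture(scope="session")
def calibration_runs():
    return CALIBRATION_RUNS


def make_actuator(ab=25.0, pwm=74.51, **kw) -> Actuator:
    return Actuator(settings=ActuatorSettings(AB_distance=ab, PWM=pwm, **kw))


def bench_ventilator(pause=0.20, raw=18.0, vt=150.0) -> VentilatorSettings:
    return VentilatorSettings(
        respiratory_rate=13.0, tidal_volume=vt, pause_fraction=pause, Raw=raw
    )


@pytest.fixture
def default_lung() -> LungSettings:
    return LungSettings(compliance=20.0)


@pytest.fixture(autouse=True)
def _numpy_print():
    np.set_printoptions(precision=8, suppress=True)
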