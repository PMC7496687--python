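import logging

import numpy as np
import pytest

from cardiosk.calcium import CalibrationParams
from cardiosk.io_model import StepProtocol, TimeSeries
from cardiosk.simulate import NoiseParams

# the clipping warnings are expected in noisy-pipeline tests; keep output clean
logging.getLogger("cardiosk.calcium").setLevel(logging.ERROR)


@pytest.fixture
def no_noise():
    return NoiseParams(sigma_current=0.0, sigma_fluor_frac=0.0, seed=0)


@pytest.fixture
def calibration():
    return CalibrationParams(fmax=1.0)  # fmin = 1/15


@pytest.fixture
def protocol():
    return StepProtocol(holding_potential=-40.0, step_potential=-10.0,
                        step_onset=50.0, step_duration=300.0)


def ts(values, dt=1.0, t0=0.0, unit="a.u."):
    return TimeSeries(t0, dt, np.asarray(values, float), unit)


@pytest.fixture
def make_ts():
    return ts
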