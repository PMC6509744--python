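import numpy as np
import pytest
from hypothesis import settings

from vineyield.color_ops import ScalarChannel
from vineyield.particles import ScaleCalibration

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def calib():
    return ScaleCalibration(pixels_per_cm=5.0)


def make_channel(values, name="b*"):
    return ScalarChannel(values=np.asarray(values, dtype=np.float64), name=name)
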