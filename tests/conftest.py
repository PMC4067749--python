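import numpy as np
import pytest

from cenquant.camera import CameraModel
from cenquant.photometry import AperturePolicy


@pytest.fixture
def default_cam():
    return CameraModel(bias_level=100.0)


@pytest.fixture
def unit_gain_cam():
    """Camera working directly in photon units (gain 1, no bias)."""
    return CameraModel(conversion_gain=1.0)


@pytest.fixture
def policy():
    return AperturePolicy()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
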