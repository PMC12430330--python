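import numpy as np
import pytest

from forcespec import Calibration, CurveSynthesisParams


@pytest.fixture
def calibration():
    """Default cantilever calibration (0.2 N/m normal, 80 N/m lateral)."""
    return Calibration()


@pytest.fixture
def curve_params():
    """Noise-free curve-synthesis parameters at the default geometry."""
    return CurveSynthesisParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
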