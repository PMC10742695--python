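import numpy as np
import pytest

from entroscan.io import AcquisitionMeta, EnvelopeFrame, RFFrame
from entroscan.phantom import default_meta


@pytest.fixture
def meta() -> AcquisitionMeta:
    """Reference acquisition: 3 MHz center, 12 MHz sampling, 2.3 mm pulse."""
    return default_meta()


@pytest.fixture
def rayleigh_envelope(meta) -> EnvelopeFrame:
    """IID Rayleigh envelope frame (fully developed speckle statistics)."""
    rng = np.random.default_rng(42)
    return EnvelopeFrame(amplitude=rng.rayleigh(1.0, (160, 24)), meta=meta)


@pytest.fixture
def small_rf(meta) -> RFFrame:
    rng = np.random.default_rng(3)
    return RFFrame(samples=rng.normal(size=(256, 16)), meta=meta)
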