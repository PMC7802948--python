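import numpy as np
import pytest

from diaus.imaging import Scale, UltrasoundFrame


@pytest.fixture
def band_frame():
    """Noise-free normalised frame with a bright band at rows [10, 30)."""
    px = np.full((100, 40), 0.1)
    px[10:30, :] = 0.9
    px[30:, :] = 0.5
    return UltrasoundFrame(px, scale=Scale.NORMALIZED_0_1, source_id="band")


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
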