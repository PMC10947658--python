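import numpy as np
import pytest
from hypothesis import settings

from openivis.core import AcquisitionSetting, ImageFrame
from openivis.virtual_instrument import presets

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def ideal_camera():
    return presets.ideal_camera()


@pytest.fixture
def plain_setting():
    return AcquisitionSetting(exposure_ms=100.0)


def make_frame(pixels, **kw) -> ImageFrame:
    """Frame from an array; scalars/2-D arrays are broadcast to H x W x 3."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 2:
        pixels = np.repeat(pixels[..., None], 3, axis=2)
    return ImageFrame(pixels=pixels, **kw)


@pytest.fixture
def uniform_frame():
    def _build(value, shape=(10, 12)):
        return make_frame(np.full(shape + (3,), float(value)))

    return _build
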