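import numpy as np
import pytest

from curtainkit.config import ImagingConfig


@pytest.fixture
def unshuttered_cfg():
    return ImagingConfig.unshuttered(frames=200)


@pytest.fixture
def two_color_cfg():
    return ImagingConfig.two_color(frames=300, shape=(16, 128))


def make_step_trace(levels, dwell, noise_sd=0.0, seed=0):
    """Piecewise-constant trace: each level held for ``dwell`` frames."""
    rng = np.random.default_rng(seed)
    x = np.repeat(np.asarray(levels, dtype=float), dwell)
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, x.size)
    return x
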