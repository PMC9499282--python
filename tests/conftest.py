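import numpy as np
import pytest

import stereodepth as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def circle_spec():
    """Study-replica circle stimulus, correlated, central, short duration."""
    return sd.preset("exp1_circle", correlation="correlated",
                     target_disparity=28.0, duration_ms=80)


@pytest.fixture
def toy_window():
    """A 16x16 pixel lattice for brute-force filter oracles."""
    return sd.Window(centre=(0.0, 0.0), shape=(16, 16), pixel_pitch=1.9)


@pytest.fixture
def toy_frames(toy_window, rng):
    """Random left/right contrast images on the toy lattice."""
    return (rng.normal(size=toy_window.shape), rng.normal(size=toy_window.shape))
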