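import numpy as np
import pytest

from bactrack import BacteriumSpec, SceneSpec
from bactrack.stack import FrameStack


@pytest.fixture
def small_straight_scene():
    """One rod moving +x at 28.26 um/s (10 px/frame), noise-free, in-frame
    for all 30 frames."""
    return SceneSpec(
        width_px=420, height_px=200, n_frames=30, noise_sd=0.0,
        bacteria=[BacteriumSpec(start_xy=(50.0, 100.0), speed=28.26,
                                heading=0.0, heading_sd_per_step=0.0)],
        rng_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stack(frames, **kw):
    return FrameStack(frames=[np.asarray(f, dtype=np.uint8) for f in frames],
                      **kw)
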