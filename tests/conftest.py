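import numpy as np
import pytest

from lesionshape import ball_mask, compute_markers


@pytest.fixture(scope="session")
def ball_10mm():
    """Digital ball of radius 10 mm on a 0.5 mm grid (r = 20 voxels)."""
    return ball_mask(10.0, 0.5)


@pytest.fixture(scope="session")
def ball_10mm_markers(ball_10mm):
    return compute_markers(ball_10mm, target_spacing=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
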