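import numpy as np
import pytest

from planargait.camera import WalkwayGeometry, side_pixels_to_world
from planargait.simulate import (DEFAULT_SIDE_CAMERA, WalkerConfig,
                                 generate_walk, render_views)


@pytest.fixture(scope="session")
def comfortable_walk():
    """Noiseless comfortable-style walk with exact ground truth."""
    return generate_walk(WalkerConfig.for_style("comfortable"))


@pytest.fixture(scope="session")
def rendered_world(comfortable_walk):
    """The comfortable walk rendered through the side camera and
    back-projected to world coordinates (noiseless, centred subject)."""
    side_px, _ = render_views(comfortable_walk, seed=0)
    return side_pixels_to_world(side_px, DEFAULT_SIDE_CAMERA,
                                WalkwayGeometry())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
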