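import numpy as np
import pytest

from wormhcs import make_scene, render_well


@pytest.fixture(scope="session")
def crowded_well():
    """One rendered 36-worm mixed-stage well, reused across tests."""
    rng = np.random.default_rng(2024)
    scene = make_scene(36, adult_fraction=0.5, rng=rng)
    images = render_well(scene, rng=rng)
    return scene, images


@pytest.fixture(scope="session")
def separated_well():
    """A rendered well whose worms were placed without any overlap."""
    rng = np.random.default_rng(77)
    scene = make_scene(12, adult_fraction=0.5, avoid_overlap=True, rng=rng)
    assert scene.overlap_events == 0
    images = render_well(scene, rng=rng)
    return scene, images
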