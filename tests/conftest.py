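import numpy as np
import pytest

import cometkit as ck


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One 512x512 scene with overlaps, debris and noise, plus its truth."""
    img, truth = ck.compose_scene(n_comets=18, overlap_rate=0.2, n_debris=8,
                                  seed=42)
    return img, truth


@pytest.fixture(scope="session")
def small_scene_result(small_scene):
    img, _ = small_scene
    return ck.analyze_image(img)


@pytest.fixture
def asym_image():
    """2x3 asymmetric fixture pinning the (row, col) convention."""
    return np.array([[1.0, 2.0, 3.0],
                     [4.0, 5.0, 6.0]])


def disc_mask(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
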