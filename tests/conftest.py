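import numpy as np
import pytest

import infantmotion as im


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free 100-frame scene with four sinusoidal limbs, plus truth."""
    spec = im.default_scene(duration=8.0, seed=3, noise_sigma=0.0, salt_pepper_prob=0.0)
    seq, gt = im.render_scene(spec)
    return spec, seq, gt


@pytest.fixture(scope="session")
def occluded_scene():
    """Same scene with two occlusion intervals (limbs hidden, not drawn)."""
    occ = {"right_hand": [(30, 45)], "left_foot": [(10, 18)]}
    spec = im.default_scene(
        duration=8.0, seed=3, noise_sigma=0.0, salt_pepper_prob=0.0, occlusions=occ
    )
    seq, gt = im.render_scene(spec)
    return spec, seq, gt


@pytest.fixture(scope="session")
def tracked_clean(clean_scene):
    """Ground-truth-provider tracking result on the clean scene."""
    _, seq, gt = clean_scene
    inits = {limb: gt.centers[limb][0] for limb in im.LIMBS}
    return im.track_all(seq, inits, gt.calibration, gt.reset_provider())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
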