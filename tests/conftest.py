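import numpy as np
import pytest

import nanosyn as ns


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """A modest neuropil scene shared by read-only tests."""
    return ns.generate_scene(ns.SceneParams(field_size_um=15, seed=21))


@pytest.fixture(scope="session")
def spot_grid_image():
    """36 isolated ~120 nm clusters rendered with the sharpest modality."""
    scene = ns.make_spot_grid_scene(36, diameter_nm=120.0, seed=7)
    return ns.render_channel_image(scene, "gsted", "pTDP43"), scene
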