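import numpy as np
import pytest

from canopypheno.image_io import RGBImage
from canopypheno.segmentation import (SegmentationConfig, learn_soil_threshold)
from canopypheno.synthetic_canopy import SceneSpec, generate_scene


@pytest.fixture
def small_scene():
    """A 256x256 synthetic canopy scene with default class colors."""
    return generate_scene(SceneSpec(width=256, height=256, seed=42))


def threshold_from_scene(scene, n_train=2000, seed=0):
    """Learn a soil threshold from pixels labeled by the scene's own truth
    mask (emulating the hand-labeled training step)."""
    rng = np.random.default_rng(seed)
    cols = scene.image.pixels.reshape(-1, 3)
    labs = scene.mask.labels.ravel()
    idx = rng.choice(cols.shape[0], min(n_train, cols.shape[0]), replace=False)
    return learn_soil_threshold(cols[idx], labs[idx] == 0)


@pytest.fixture
def scene_config(small_scene):
    return SegmentationConfig(threshold_model=threshold_from_scene(small_scene),
                              seed=7)


@pytest.fixture
def checker_image():
    """A 6x6 image: plant-green square centered on soil brown."""
    px = np.full((6, 6, 3), (110, 85, 65), dtype=np.uint8)
    px[2:4, 2:4] = (60, 120, 50)
    return RGBImage(px, source_id="checker")
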