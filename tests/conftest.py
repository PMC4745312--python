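import numpy as np
import pytest

from cellcull import synthetic
from cellcull.segmentation import ObjectRecord
from cellcull.slidemap import to_grayscale


def make_object(crop, mask, label=None, object_id=0) -> ObjectRecord:
    """Wrap a rendered (crop, mask) pair as an ObjectRecord."""
    return ObjectRecord(
        object_id=object_id, mask=np.asarray(mask, bool),
        bbox=(0, 0, mask.shape[0], mask.shape[1]),
        boundary=np.empty((0, 2), dtype=int),
        crop=crop, gray_crop=to_grayscale(crop), label=label)


@pytest.fixture(scope="session")
def suitable_object():
    crop, mask = synthetic.render_cell(
        "suitable", 30, 2.0, np.random.default_rng(7))
    return make_object(crop, mask, label="suitable")


@pytest.fixture(scope="session")
def folded_object():
    crop, mask = synthetic.render_cell(
        "folded", 30, 8.0, np.random.default_rng(7))
    return make_object(crop, mask, label="unsuitable")


@pytest.fixture(scope="session")
def small_scene():
    """A small 2x2-tile scene with a handful of objects, for fast tests."""
    spec = synthetic.SceneSpec(
        image_height=512, image_width=640, tile_rows=2, tile_cols=2,
        n_suitable=3, n_unsuitable=3, cell_radius_range=(14.0, 22.0), seed=11)
    tiles, background, truth = synthetic.generate_slide_scene(spec)
    return spec, tiles, background, truth
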