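import warnings

import numpy as np
import pytest

from avhue import (
    SceneConfig,
    classify_vesicles,
    generate_scene,
    segment_field,
)

#: Compact scene reused across unit tests (full-size scenes run in the
#: acceptance tests).
# Default per-neuron composition: the perikarya-mean threshold rule needs a
# realistic vesicle load to sit usefully above the soma base signal.
SMALL_SCENE = dict(width_px=512, height_px=512, n_neurons=6, rng_seed=11)


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(SceneConfig(**SMALL_SCENE))


@pytest.fixture(scope="session")
def segmented_small(small_scene):
    field, mask, gt = small_scene
    vesicles, thresholds, labeled = segment_field(field, mask, n_sample=mask.n_rois)
    classify_vesicles(vesicles, thresholds, bit_depth=field.bit_depth)
    return field, mask, gt, vesicles, thresholds, labeled


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
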