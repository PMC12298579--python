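import numpy as np
import pytest

from canopyield.fixtures import PRESETS, generate_canopy_scene, generate_yield_dataset
from canopyield.segmentation import segment_canopy
from canopyield.types import AllometryParams
from canopyield.yield_models import compare_models, records_from_arrays

#: seed of the shared noisy fixture dataset; the whole suite uses one value
FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def mid_scene():
    """One stress-free mid-growth scene at the desk-scale preset."""
    return generate_canopy_scene(PRESETS["desk1024"], "mid", seed=0)


@pytest.fixture(scope="session")
def mid_scene_segmented(mid_scene):
    return segment_canopy(mid_scene.image)


@pytest.fixture(scope="session")
def noisy_records():
    """Default 60-plant allometric dataset (noise_cv = 0.12)."""
    df = generate_yield_dataset(AllometryParams(seed=FIXTURE_SEED))
    return records_from_arrays(df.true_area_cm2, df.fresh_weight_g)


@pytest.fixture(scope="session")
def noisy_comparison(noisy_records):
    """Full 28-model comparison on the default fixture dataset."""
    return compare_models(noisy_records, fraction=0.25, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def noiseless_records():
    df = generate_yield_dataset(AllometryParams(noise_cv=0.0, seed=FIXTURE_SEED))
    return records_from_arrays(df.true_area_cm2, df.fresh_weight_g)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
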