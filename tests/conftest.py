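import numpy as np
import pytest

from saffronvision.pipeline import build_feature_table, RunConfig
from saffronvision.preprocess import PreprocessParams
from saffronvision.synthetic import default_scene_params, generate_image


@pytest.fixture(scope="session")
def scaled_pre() -> PreprocessParams:
    """Preprocessing constants scaled from the full camera frame to the
    512x512 synthetic canvas (pixel-count thresholds scale with area)."""
    return PreprocessParams(min_component_area=64, structuring_radius=2)


@pytest.fixture(scope="session")
def pushal_scene():
    params = default_scene_params("Pushal", seed=1)
    image, gt = generate_image(params)
    return image, gt, params


@pytest.fixture(scope="session")
def synthetic_table(scaled_pre):
    """Feature table for a balanced 30/30/30 synthetic dataset (one build
    per session; several suites reuse it)."""
    config = RunConfig(
        counts={"Pushal": 30, "Negin": 30, "Sargol": 30},
        preprocess=scaled_pre,
        seed=11,
    )
    return build_feature_table(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
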