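import dataclasses

import numpy as np
import pytest

from mitoqc import quantify, synthetic
from mitoqc.classifier import split_train_test, train_morphology_model
from mitoqc.io_config import RunConfig


@pytest.fixture(scope="session")
def default_cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def fast_cfg():
    """Default parameters but a short mtry search, for unit tests that only
    need *a* trained morphology model."""
    return dataclasses.replace(RunConfig(), rf_tune_iters=2)


@pytest.fixture(scope="session")
def clean_scene():
    """A noise-free synthetic field with ground truth."""
    cfg = synthetic.SceneConfig(size_px=384, n_cells=3, n_objects=40, seed=11).noise_free()
    return synthetic.generate_scene(cfg)


@pytest.fixture(scope="session")
def pixel_models(default_cfg):
    """Pixel models trained on an independent noise-free scene."""
    train_scene = synthetic.generate_scene(
        synthetic.SceneConfig(size_px=384, n_cells=3, n_objects=40, seed=99).noise_free()
    )
    return quantify.train_models_from_scene(train_scene, default_cfg, seed=5)


@pytest.fixture(scope="session")
def labeled_table_small():
    return synthetic.generate_labeled_feature_table(400, seed=7)


@pytest.fixture(scope="session")
def morphology_model(labeled_table_small, fast_cfg):
    train, _ = split_train_test(labeled_table_small, 0.8, seed=1)
    return train_morphology_model(train, fast_cfg, seed=1)


@pytest.fixture(scope="session")
def all_models(pixel_models, morphology_model):
    return {**pixel_models, "morphology_model": morphology_model}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
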