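"""Shared fixtures.

The desk-scale experiment (200 phantoms, 32^3 inputs, 140/20/40 ranked-id
split, seed 17) is expensive, so it is built once per session and shared by
every test that needs a trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from mridensity import phantom as ph
from mridensity.experiment import ExperimentConfig, prepare_dataset
from mridensity import density_cnn as cnn


@pytest.fixture(scope="session")
def small_phantom() -> ph.Phantom:
    return ph.make_phantom(ph.PhantomSpec(target_density=15.0, seed=3))


@pytest.fixture(scope="session")
def noiseless_spec() -> ph.PhantomSpec:
    return ph.PhantomSpec(target_density=20.0, noise_sigma=0.0, bias_amplitude=0.0, seed=5)


@pytest.fixture(scope="session")
def tiny_experiment_config() -> ExperimentConfig:
    """Smallest end-to-end configuration: 12 phantoms, 16^3 inputs, 2 epochs."""
    from dataclasses import replace

    base = ExperimentConfig()
    return ExperimentConfig(
        n_phantoms=12,
        split_sizes=(7, 2, 3),
        phantom_template=ph.PhantomSpec(grid_shape=(24, 24, 24)),
        cnn_config=replace(base.cnn_config, input_shape=(16, 16, 16), epochs=2, base_filters=4),
        augmentation=cnn.AugmentationSpec(max_translation_voxels=2),
        n_explained=1,
        master_seed=11,
    )


@pytest.fixture(scope="session")
def desk_config() -> ExperimentConfig:
    """The desk-scale density-recovery experiment: 200 phantoms at 32^3,
    densities uniform in [2, 40], split 140/20/40 on ranked id, seed 17."""
    return ExperimentConfig(master_seed=17)


@pytest.fixture(scope="session")
def desk_data(desk_config):
    return prepare_dataset(desk_config)


@pytest.fixture(scope="session")
def desk_model(desk_config, desk_data):
    from dataclasses import replace

    cfg = replace(desk_config.cnn_config, seed=desk_config.stage_seed("cnn"))
    return cnn.train(
        desk_data["volumes"],
        desk_data["fcm_labels"],
        desk_data["split"],
        cfg,
        aug=desk_config.augmentation,
        normalization=desk_config.normalization,
    )


@pytest.fixture(scope="session")
def desk_predictions(desk_model, desk_data):
    split = desk_data["split"]
    est = np.array([cnn.predict(desk_model, desk_data["volumes"][i]) for i in split.test_ids])
    truth = np.array([desk_data["fcm_labels"][i] for i in split.test_ids])
    return est, truth
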