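"""Shared fixtures: synthetic datasets and (expensive) trained models.

The end-to-end trainings are session-scoped so the reduced-model fit is
paid once and reused by the training, inference and acceptance tests.
"""

import numpy as np
import pytest

from slumbernet.augment import AugmentConfig
from slumbernet.model import ModelConfig, build_model
from slumbernet.preprocess import preprocess_dataset
from slumbernet.synthetic import (
    StageSignalParams,
    TransitionModel,
    sample_stage_sequence,
    synthesize_epochs,
)
from slumbernet.training import stratified_kfold, train_fold

#: Reduced test-scale configuration (2 blocks, 4 starting maps, lr 1e-4,
#: 10 passes, batch 8).
REDUCED_CONFIG = ModelConfig.reduced(seed=0)

N_SYNTH_EPOCHS = 3000
SYNTH_SEED = 1


def make_dataset(n_epochs, seed, artifact_rate=0.02):
    model = TransitionModel(artifact_rate=artifact_rate, seed=seed)
    labels = sample_stage_sequence(n_epochs, model)
    epochs = synthesize_epochs(labels, StageSignalParams(), seed=seed)
    return preprocess_dataset(epochs)


@pytest.fixture(scope="session")
def synth_dataset():
    """~3000 default synthetic epochs, preprocessed (artifacts removed)."""
    return make_dataset(N_SYNTH_EPOCHS, SYNTH_SEED)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 120-epoch dataset for structural tests."""
    return make_dataset(120, seed=7, artifact_rate=0.0)


@pytest.fixture(scope="session")
def fold_splits(synth_dataset):
    return stratified_kfold(synth_dataset.labels, k=5, seed=0)


@pytest.fixture(scope="session")
def trained_fold(synth_dataset, fold_splits):
    """Reduced model trained without augmentation on fold 1."""
    model = build_model(REDUCED_CONFIG)
    hist = train_fold(model, fold_splits[0], synth_dataset, REDUCED_CONFIG, aug=None)
    return model, hist


@pytest.fixture(scope="session")
def trained_fold_augmented(synth_dataset, fold_splits):
    """Same fold trained with the default augmentation on the training side."""
    model = build_model(REDUCED_CONFIG)
    hist = train_fold(model, fold_splits[0], synth_dataset, REDUCED_CONFIG,
                      aug=AugmentConfig(seed=0))
    return model, hist


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
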