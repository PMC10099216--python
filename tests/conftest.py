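"""Shared fixtures: small synthetic cohorts and a micro-scale experiment run."""

from __future__ import annotations

import numpy as np
import pytest

from mmldms.orchestration import (
    ExperimentConfig,
    build_spectrogram_dataset,
    cross_validate,
    desk_scale_stft,
)
from mmldms.classifiers import CnnConfig
from mmldms.preprocessing import WindowSpec
from mmldms.synthetic import default_synth_config, generate_cohort


@pytest.fixture(scope="session")
def synth_config():
    return default_synth_config()


@pytest.fixture(scope="session")
def small_cohort(synth_config):
    """8 records (one per disorder), 6 epochs each."""
    return generate_cohort(1, 6, synth_config, seed=7)


@pytest.fixture(scope="session")
def micro_dataset(small_cohort):
    """Non-overlapping 10-s windows, 32x32 log-frequency spectrograms."""
    return build_spectrogram_dataset(
        small_cohort,
        window=WindowSpec(window_len=10.0, stride=10.0, epoch_len=30.0),
        stft=desk_scale_stft(32),
    )


def micro_config(seed: int = 3, n_repeats: int = 1) -> ExperimentConfig:
    return ExperimentConfig(
        mode="mml_dms2",
        cnn=CnnConfig(
            architecture="small_test", input_size=32, learning_rate=0.01,
            batch_size=10, max_epochs=2, early_stopping_patience=2, seed=seed,
        ),
        nn_max_epochs=5,
        image_size=32,
        n_repeats=n_repeats,
        seed=seed,
    )


@pytest.fixture(scope="session")
def micro_run(micro_dataset):
    """One full-suite micro experiment (all systems, one repeat)."""
    return cross_validate(micro_config(), micro_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
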