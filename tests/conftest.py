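"""Shared fixtures.

The session-scoped ``experiment`` fixture runs the expensive part of the
study once — generating a 360-epoch recording with the reference class
mix, preprocessing it and extracting all 30 features — and is shared by
the qualitative-trend and classification tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from earsleep.pipeline import extract_features
from earsleep.preprocess import preprocess_for_classification
from earsleep.synthetic import generate_recording, stage_mix_sequence

EXPERIMENT_SEED = 42
EXPERIMENT_EPOCHS = 360


@pytest.fixture(scope="session")
def experiment() -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table and stage labels for the 360-epoch synthetic study.

    Class mix approximates the reference pool (W:67, N1:46, N2:140, N3:40
    scaled to 360 epochs); generation, preprocessing and feature
    extraction all run with the shipped defaults.
    """
    sequence = stage_mix_sequence(EXPERIMENT_EPOCHS, seed=EXPERIMENT_SEED)
    recording, hypnogram = generate_recording(sequence, seed=EXPERIMENT_SEED)
    epochset = preprocess_for_classification(recording.samples[0], recording.fs)
    features = extract_features(epochset)
    labels = np.array([hypnogram.labels[i] for i in features.index])
    complete = ~features.isna().any(axis=1).to_numpy()
    return features[complete], labels[complete]
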