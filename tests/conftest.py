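"""Shared fixtures: synthetic datasets and trained detectors.

The session-scoped ``trained_small`` detector is the desk-scale study model:
small preset trained on 200 synthetic 4 s recordings at 10 dB SNR (seed 0).
Training takes a couple of minutes on one CPU and is shared by every test that
needs a working detector.
"""

from __future__ import annotations

import pytest

from auscult import detection, synthesis

TRAIN_N = 200
HELDOUT_N = 50
SNR_DB = 10.0


@pytest.fixture(scope="session")
def train_set():
    return synthesis.make_detector_dataset(TRAIN_N, seed=0, snr_db=SNR_DB)


@pytest.fixture(scope="session")
def heldout_set():
    return synthesis.make_detector_dataset(HELDOUT_N, seed=1000, snr_db=SNR_DB)


@pytest.fixture(scope="session")
def trained_small(train_set):
    model = detection.build_detector("small", seed=0)
    history = detection.train_detector(model, train_set)
    detection.select_class_thresholds(model, train_set)
    return model, history


@pytest.fixture(scope="session")
def mini_model():
    """A cheaply trained detector for behavioural (non-performance) tests."""
    data = synthesis.make_detector_dataset(40, seed=7, snr_db=SNR_DB)
    model = detection.build_detector("small", seed=7)
    detection.train_detector(model, data, epochs=10)
    return model
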