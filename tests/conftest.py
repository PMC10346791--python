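"""Shared fixtures: synthetic datasets and small model configurations.

The expensive fixtures (the 120-recording synthetic dataset and its
preprocessed segments) are session-scoped so the distribution-level tests
and the end-to-end learning test share one generation pass.
"""

import numpy as np
import pytest

from eegwavenet.model import ModelConfig
from eegwavenet.preprocess import preprocess_dataset
from eegwavenet.recordings import Recording
from eegwavenet.synthetic import SyntheticSpec, simulate_dataset


@pytest.fixture(scope="session")
def synth_dataset_120():
    """Default-condition synthetic dataset: n=120, half abnormal, seed 7."""
    spec = SyntheticSpec(n_recordings=120, seed=7)
    recs, manifest, events = simulate_dataset(spec)
    return recs, manifest, events


@pytest.fixture(scope="session")
def segments_10s(synth_dataset_120):
    """TUAB-style preprocessing of the session dataset at 10-s segments."""
    recs, _, _ = synth_dataset_120
    return preprocess_dataset(recs, profile="tuab", seg_seconds=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_model_config():
    """A miniature architecture used for gradient and property checks."""
    return ModelConfig(
        n_input_channels=3, input_len=40, window_len=10,
        block_dilations=((1, 2), (1, 2)), conv_filters=4, kernel_size=3,
        pool_factor=2, path1_rnn_units=5, window_rnn_units=4,
        path2_rnn_units=5, path2_dense_units=3, dropout=0.0, dtype="float64",
    )


def make_recording(rng, n_channels=21, fs=250.0, duration=4.0,
                   labels=None, class_label="unknown"):
    """A random recording with standard 10-20 labels (helper, not a fixture)."""
    from eegwavenet.synthetic import ELECTRODES_21

    if labels is None:
        labels = list(ELECTRODES_21[:n_channels])
    n = int(duration * fs)
    sig = rng.standard_normal((len(labels), n)) * 10.0
    return Recording(signal=sig, fs=fs, labels=labels,
                     subject_id="fix", class_label=class_label)
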