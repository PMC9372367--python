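"""Shared fixtures: synthetic segments and a small trained classifier."""

import numpy as np
import pytest

from fetalcoupling.beat_series import SegmentPair, encode_segment, segment_minutes
from fetalcoupling.coupling_label import SUPPORTED_RATIOS
from fetalcoupling.deepmodel import CouplingClassifier, ModelConfig
from fetalcoupling.synth import GeneratorConfig, generate_pair


def make_segment(ratio, jitter=0.0, seed=0, duration=60.0) -> SegmentPair:
    """First 1-min segment of a freshly generated coupled record."""
    maternal, fetal, _ = generate_pair(
        GeneratorConfig(ratio=ratio, phase_jitter_sd=jitter, seed=seed, duration=duration)
    )
    return segment_minutes(maternal, fetal)[0]


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    """Reduced-rate config: 50 Hz grid (L=3000), duration-preserving kernels."""
    return ModelConfig(fs=50.0, seed=11, max_epochs=8)


@pytest.fixture(scope="session")
def separable_dataset(tiny_config):
    """30 zero-jitter segments (10 per ratio) encoded at the tiny rate."""
    X, y, segs = [], [], []
    for ci, ratio in enumerate(SUPPORTED_RATIOS):
        for i in range(10):
            seg = make_segment(ratio, jitter=0.0, seed=100 * ci + i)
            enc = encode_segment(seg, fs=tiny_config.fs)
            X.append(enc.grid)
            y.append(ci)
            segs.append(enc)
    return np.stack(X).astype(np.float32), np.array(y), segs


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_config, separable_dataset):
    """Classifier trained to separate the zero-jitter dataset."""
    X, y, _ = separable_dataset
    model = CouplingClassifier(tiny_config)
    model.fit(X, y)
    return model


@pytest.fixture(scope="session")
def generalizing_model(tiny_config):
    """Classifier trained on 120 distinct jittered records.

    Cross-record generalization needs record diversity, so this fixture
    trades a little runtime for 40 fresh records per class.
    """
    X, y = [], []
    for ci, ratio in enumerate(SUPPORTED_RATIOS):
        for i in range(40):
            seg = make_segment(ratio, jitter=0.02, seed=5000 + 100 * ci + i)
            X.append(encode_segment(seg, fs=tiny_config.fs).grid)
            y.append(ci)
    model = CouplingClassifier(
        ModelConfig(fs=tiny_config.fs, seed=13, max_epochs=15)
    )
    model.fit(np.stack(X).astype(np.float32), np.array(y))
    return model
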