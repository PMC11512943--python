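"""Shared fixtures: toy datasets, small cohorts, pre-trained tiny models."""

from __future__ import annotations

import numpy as np
import pytest

from eegens.models import EpochClassifier, EpochDataset, ModelSpec, TrainingConfig
from eegens.synthdata import CohortSpec, generate_cohort

#: Small model used wherever a test needs "a classifier" rather than capacity.
SMALL_SPEC = ModelSpec(width=4, depth=2, kernel_sizes=(3, 7, 15))
FAST_CFG = TrainingConfig(max_iterations=8, batch_size=32, seed=0)


def make_blobs(n, rng, n_channels=4, samples=100, sep=1.0, noise=0.3):
    """Linearly separable toy epochs: two Gaussian blobs rendered as
    constant-in-time channel levels."""
    y = rng.integers(0, 2, n)
    mu = np.where(y[:, None] == 1, sep, -sep)
    levels = mu + noise * rng.standard_normal((n, n_channels))
    X = np.repeat(levels[:, :, None], samples, axis=2)
    sids = np.array([f"T{i:03d}" for i in range(n)], dtype=object)
    return EpochDataset(X=X, y=y, subject_ids=sids)


@pytest.fixture(scope="session")
def blob_data():
    rng = np.random.default_rng(42)
    return make_blobs(160, rng), make_blobs(48, rng)


@pytest.fixture(scope="session")
def trained_small(blob_data):
    tr, va = blob_data
    return EpochClassifier(SMALL_SPEC).fit(tr, va, FAST_CFG)


@pytest.fixture(scope="session")
def trained_ads(blob_data):
    tr, va = blob_data
    spec = ModelSpec(width=4, depth=2, kernel_sizes=(3, 7, 15),
                     ads=True, dropout_rate=0.5)
    return EpochClassifier(spec).fit(tr, va, FAST_CFG)


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 balanced subjects, 4 channels, 100 Hz, 44 s, alpha effect."""
    spec = CohortSpec(
        n_subjects=12, n_channels=4, sampling_rate=100.0, duration=44.0,
        band_effects={"alpha": (1.0, 1.6), "theta": (1.0, 1.0)},
        noise_sd=3.0, seed=21,
    )
    return spec, generate_cohort(spec)
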