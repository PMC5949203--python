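"""Shared fixtures.

The full-scale synthetic cohorts (17+8 subjects, 100 trials/condition,
128 channels at 1 kHz) take ~2 minutes each to generate and preprocess, so
they are session-scoped and shared by the power/null/sweep tests.
"""

import numpy as np
import pytest

from roismining.cli import RunConfig, preprocess_cohort
from roismining.preprocess import Recording


def make_recording(
    n_channels=8,
    n_samples=4000,
    rate_hz=1000.0,
    events=((1000, "sound"), (2500, "nonsound")),
    eye=("EOG1",),
    seed=0,
    amplitude=5.0,
):
    """Small random recording with one designated eye channel."""
    rng = np.random.default_rng(seed)
    labels = [f"CH{i}" for i in range(n_channels - len(eye))] + list(eye)
    data = rng.standard_normal((n_channels, n_samples)) * amplitude
    return Recording(
        data=data,
        rate_hz=rate_hz,
        channel_labels=labels,
        eye_channel_labels=tuple(eye),
        events=list(events),
    )


@pytest.fixture
def tiny_recording():
    return make_recording()


@pytest.fixture(scope="session")
def planted_cohort_cache():
    """Preprocessed default cohort with the planted group effect (delta 0.5)."""
    cfg = RunConfig(simulate=True, seed=1, measure="xcor", classifier="knn")
    return preprocess_cohort(cfg), cfg


@pytest.fixture(scope="session")
def null_cohort_cache():
    """Preprocessed cohort with no group effect (delta 0)."""
    cfg = RunConfig(simulate=True, seed=2, effect_delta=0.0, measure="xcor", classifier="knn")
    return preprocess_cohort(cfg), cfg
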