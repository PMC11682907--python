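"""Shared fixtures: one simulated study (with injected artifacts) reused
across preprocessing, scoring and modelling tests."""

from __future__ import annotations

import numpy as np
import pytest

from gazebias.preproc import preprocess_dataset, qc_exclude
from gazebias.synth import ArtifactSpec, simulate_dataset


@pytest.fixture(scope="session")
def study():
    """A 16-subject simulated study with a few injected artifacts."""
    ds = simulate_dataset(
        n_control=10,
        n_mdd=6,
        artifacts=ArtifactSpec(
            dropout_rate=0.03,
            p_start_in_aoi=0.03,
            p_slow_latency=0.03,
            p_short_trial=0.02,
            rng_seed=11,
        ),
        seed=3,
    )
    return ds


@pytest.fixture(scope="session")
def study_dwell(study):
    return preprocess_dataset(study.samples, study.trials)


@pytest.fixture(scope="session")
def study_qc(study_dwell):
    return qc_exclude(study_dwell)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
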