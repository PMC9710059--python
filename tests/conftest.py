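"""Shared fixtures: small synthetic ensembles and preprocessed datasets."""

from __future__ import annotations

import numpy as np
import pytest

from leadconv.preprocess import SplitSpec, preprocess_pipeline, subject_split
from leadconv.synth import SynthConfig, generate_dataset

LIMB_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF")


@pytest.fixture(scope="session")
def small_records():
    """A small multi-subject 12-lead ensemble (250 Hz to keep tests quick)."""
    config = SynthConfig(n_subjects=6, records_per_subject=2, duration_s=10.0,
                         fs=250.0, seed=7)
    return generate_dataset(config)


@pytest.fixture(scope="session")
def clean_records():
    """Noise-free ensemble: limb-lead identities hold to machine precision."""
    config = SynthConfig(n_subjects=5, records_per_subject=1, duration_s=8.0,
                         fs=250.0, noise_sd=0.0, wander_amp=0.0, seed=3)
    return generate_dataset(config)


@pytest.fixture(scope="session")
def limb_dataset(small_records):
    """Preprocessed limb-lead segments (2.5 s windows at 250 Hz)."""
    return preprocess_pipeline(small_records, window_seconds=2.5,
                               fs_target=250.0, leads=LIMB_LEADS)


@pytest.fixture(scope="session")
def limb_splits(small_records):
    tr, va, te = subject_split(small_records, SplitSpec(seed=1))
    mk = lambda recs: preprocess_pipeline(
        recs, window_seconds=2.5, fs_target=250.0, leads=LIMB_LEADS)
    return mk(tr), mk(va), mk(te)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
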