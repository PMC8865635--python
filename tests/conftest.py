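"""Shared fixtures: scaled-down designs and cohorts.

Simulated fixtures use reduced sampling rates, stimulus counts and
repetition numbers so the whole suite runs on one CPU in minutes; the
structural constants under test (channel layout, trial bookkeeping,
half-open epoch convention) are exercised at full scale where they are the
point of the test.
"""

import numpy as np
import pytest

from eegmvpa import (DecoderConfig, GroupEffectSpec, PreprocessConfig,
                     SyntheticDesign, generate_subject, preprocess_epochs)

ANALYSIS_SFREQ = 100.0  # Hz; scaled-down rate for simulated cohorts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_design():
    """4 + 4 stimuli, 3 runs, 100 Hz: fast but structurally complete."""
    return SyntheticDesign(n_runs=3, n_animate=4, n_inanimate=4,
                           sfreq_acquisition=ANALYSIS_SFREQ)


@pytest.fixture
def small_effects():
    return GroupEffectSpec(latency_jitter_ms=0.0, amplitude_jitter_sd=0.0)


@pytest.fixture
def quick_decoder():
    return DecoderConfig(n_repetitions=20, seed=0)


@pytest.fixture
def no_filter_config():
    """Preprocessing for data already sampled below the low-pass band."""
    return PreprocessConfig(lowpass_hz=None, resample_hz=None)


@pytest.fixture
def small_subject(small_design, small_effects):
    return generate_subject(small_design, small_effects, "HC", seed=7)


@pytest.fixture
def small_preprocessed(small_subject, no_filter_config):
    return preprocess_epochs(small_subject.dataset, no_filter_config)
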