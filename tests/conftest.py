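"""Shared fixtures: reference calls and signatures reused across test modules.

Call synthesis is the slowest thing in the suite, so the canonical calls are
session-scoped.
"""

import numpy as np
import pytest

from rivalcall import acoustics, synth


@pytest.fixture(scope="session")
def medium_signature() -> synth.CallSignature:
    """The 'average male' signature: 1.7 Hz, 14 pulses, Q25 643 Hz."""
    return synth.CallSignature(
        male_id="AVG",
        pulse_rate=1.7,
        n_pulses=14,
        centroid_target=1700.0,
        q25_target=643.0,
        jitter=0.0,
    )


@pytest.fixture(scope="session")
def medium_call(medium_signature) -> acoustics.CallWaveform:
    """A jitter-free average-male call at the field recording rate."""
    return synth.simulate_call(medium_signature, sample_rate=48000.0, seed=11)


@pytest.fixture(scope="session")
def medium_call_16k(medium_signature) -> acoustics.CallWaveform:
    """Same signature at a lighter sample rate for cheaper tests."""
    return synth.simulate_call(medium_signature, sample_rate=16000.0, seed=11)


@pytest.fixture(scope="session")
def medium_features(medium_call) -> acoustics.CallFeatures:
    return acoustics.extract_features(medium_call)


def gaussian_feature_clusters(n_labels, calls_per_label, separation, seed, n_features=9):
    """Label clusters in feature space without audio synthesis: cheap pDFA input."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, separation, size=(n_labels, n_features))
    X = np.vstack(
        [centers[i] + rng.normal(0.0, 1.0, size=(calls_per_label, n_features))
         for i in range(n_labels)]
    )
    y = np.repeat([f"M{i:02d}" for i in range(n_labels)], calls_per_label)
    return X, y
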