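"""Shared fixtures: phantom material and a trained desk-scale segmenter.

The trained baseline is expensive (minutes on one CPU), so it is built
once per session and shared by the training-recovery and continual-
learning tests.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from glottikit.experiments import train_baseline
from glottikit.phantom import PhantomSpec, generate_recording

# Property tests assert invariants; derandomize so runs are reproducible.
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_phantom():
    """A short clean tier-2 phantom recording (64 frames, 128x128)."""
    return generate_recording(PhantomSpec(T=64, tier=2, seed=7))


@pytest.fixture(scope="session")
def baseline_model():
    """Desk-scale segmenter trained on the packaged 500-frame corpus."""
    return train_baseline(seed=0)
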