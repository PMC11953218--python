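"""Shared fixtures: montages and small synthetic datasets.

Everything is generated programmatically; session scope keeps the
expensive 27-subject scenarios to a single build.
"""

from __future__ import annotations

import numpy as np
import pytest

import tepstates as tp


@pytest.fixture(scope="session")
def montage74():
    return tp.standard_montage_1010()


@pytest.fixture(scope="session")
def small_montage():
    """Minimal 8-channel montage for cheap unit tests."""
    rng = np.random.default_rng(42)
    pos = rng.standard_normal((8, 3))
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return tp.Montage(tuple(f"ch{i}" for i in range(8)), pos)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """3 subjects, 6 true maps, zero noise/jitter: exact-recovery regime."""
    ds, truth = tp.make_fixture_dataset(
        "clean6", seed=7, n_subjects=3, noise_sd=0.0,
        jitter_sd_ms=0.0, spatial_noise=0.0, latency_scale_sd=0.0,
    )
    return ds, truth


@pytest.fixture(scope="session")
def clean6_small():
    """Reduced clean6 (10 subjects) for mid-weight integration tests."""
    return tp.make_fixture_dataset("clean6", seed=11, n_subjects=10)
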