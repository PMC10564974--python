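"""Shared fixtures.

The desk-scale ensemble (2,500-entry library, 30 epochs) is expensive
(~4 min) and is therefore built once per session, lazily, for the tests
that need a trained classifier.
"""
from __future__ import annotations

import numpy as np
import pytest

import dtews
from dtews.nn import NetworkConfig


@pytest.fixture(scope="session")
def small_library():
    """120-entry library for fast structural tests."""
    return dtews.build_library(20, 20, rng_seed=101)


@pytest.fixture(scope="session")
def desk_library():
    """2,500-entry training library (416 models per class, 420 nulls)."""
    return dtews.build_library(416, 420, rng_seed=7)


@pytest.fixture(scope="session")
def desk_ensemble(desk_library):
    """Two-member ensemble trained at desk scale (30 epochs each)."""
    return dtews.train_ensemble(
        desk_library, NetworkConfig.desk_scale(), rng_seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
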