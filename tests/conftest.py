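"""Shared fixtures: phantom pairs and the multi-seed benchmark table.

The benchmark run is expensive (two full registrations per seed), so it is
computed once per session and shared by every test that audits it.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from vpmmi.phantom import PhantomParams, make_phantom_pair, run_benchmark
from vpmmi.registration import register_vpmmi
from vpmmi.types import RegistrationConfig


@pytest.fixture(scope="session")
def default_pair():
    """One default-condition phantom pair (speckle on, modality remap)."""
    return make_phantom_pair(0)


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free phantom settings (modality gap kept, all noise off)."""
    return replace(PhantomParams(), noise_sd=0.0, speckle=0.0, landmark_sd=0.0)


@pytest.fixture(scope="session")
def benchmark_table():
    """10-seed default-condition benchmark: VPMMI and VMI per seed."""
    table, summary = run_benchmark(10, PhantomParams(), RegistrationConfig(),
                                   base_seed=0)
    assert (table["error"] == "").all(), table["error"].tolist()
    return table, summary


@pytest.fixture(scope="session")
def clean_run(clean_params):
    """Zero-noise, exact-landmark registration of phantom seed 0."""
    pair = make_phantom_pair(0, clean_params)
    result = register_vpmmi(pair.fixed, pair.moving, pair.fixed_mask,
                            pair.moving_mask, pair.fixed_lm, pair.moving_lm)
    return pair, result


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
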