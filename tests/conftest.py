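"""Shared fixtures: one canonical simulated trial per session, plus reduced
pipeline runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from templatesig import (add_noise, canonical_initial_state, canonical_params,
                         compute_states, build_library, identify_signatures,
                         reduced_config, simulate)

N_STRIDES = 70


@pytest.fixture(scope="session")
def params():
    return canonical_params()


@pytest.fixture(scope="session")
def canonical_trial(params):
    """Noise-free canonical trial, ~70 strides (~8600 samples at 120 Hz)."""
    return simulate(params, canonical_initial_state(params),
                    n_strides=N_STRIDES)


@pytest.fixture(scope="session")
def noisy_trial(canonical_trial):
    """Canonical trial with 1 mm marker-level position noise."""
    return add_noise(canonical_trial, 1e-3, seed=7)


@pytest.fixture(scope="session")
def canonical_states(canonical_trial):
    return compute_states(canonical_trial)


@pytest.fixture(scope="session")
def canonical_library(canonical_states):
    return build_library(canonical_states)


@pytest.fixture(scope="session")
def pipeline_config():
    """Desk-scale pipeline configuration: 600 cluster seeds, 400 neighbors,
    same 3600-sample held-out set as the full-scale protocol."""
    return reduced_config(n_train_centroids=600, k=400, n_test=3600)


@pytest.fixture(scope="session")
def report_clean(canonical_trial, pipeline_config):
    return identify_signatures(canonical_trial, pipeline_config, seed=1,
                               condition="clean")


@pytest.fixture(scope="session")
def report_noisy(noisy_trial, pipeline_config):
    return identify_signatures(noisy_trial, pipeline_config, seed=1,
                               condition="noisy")
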