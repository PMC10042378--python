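"""Shared fixtures.

The heavy study artifacts (training-bank chain vectors, brute-force trials
of the agreement presets) are session-scoped: several acceptance tests
share them, and each takes tens of seconds to build.
"""

import numpy as np
import pytest
from hypothesis import settings

import gaitrisk as gr
from gaitrisk import study

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def linear_cfg():
    """A walker whose return map is effectively linear (huge saturation),
    convenient for closed-form checks."""
    return gr.WalkerConfig(contraction=0.5, input_gain=1.0, fixed_point=0.0,
                           failure_boundary=0.15, saturation=1e3,
                           grid_halfwidth=0.15, grid_spacing=0.015,
                           seed=11, name="linear")


@pytest.fixture
def fragile_cfg():
    return gr.load_preset("fragile")


@pytest.fixture(scope="session")
def training_conditions():
    """Chain-side artifacts for all 60 training conditions (no Lyapunov)."""
    return study.condition_bank("train")


@pytest.fixture(scope="session")
def norm_record(training_conditions):
    return study.training_normalization(training_conditions)


@pytest.fixture(scope="session")
def agreement_data(training_conditions, norm_record):
    """Chain-vs-brute comparisons plus the underlying brute trials for the
    agreement presets (200 x 50-step segments each)."""
    results, trials = study.agreement_study(
        training_conditions, norm_record, seed=20260929)
    return results, trials


@pytest.fixture(scope="session")
def study_model(training_conditions):
    """Combined fall-risk model (no Lyapunov variant) fitted on the
    training bank."""
    return study.fit_study_model(training_conditions, seed=20260929)
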