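"""Shared fixtures: small synthetic cohorts and analysis configurations."""

from __future__ import annotations

import numpy as np
import pytest

from myosynergy.config import PipelineConfig
from myosynergy.synthetic import CohortConfig, generate_ground_truth


@pytest.fixture(scope="session")
def small_cohort_config() -> CohortConfig:
    """Reduced-size study conditions for fast tests (protocol structure intact)."""
    return CohortConfig(discrete_reps=6, circle_cycles=3, speed_reps=2)


@pytest.fixture(scope="session")
def noiseless_cohort_config(small_cohort_config) -> CohortConfig:
    return small_cohort_config.noiseless()


@pytest.fixture(scope="session")
def fast_pipeline_config() -> PipelineConfig:
    return PipelineConfig(nmf_restarts=5, nmf_max_iter=400)


@pytest.fixture(scope="session")
def noiseless_limbs(noiseless_cohort_config):
    return generate_ground_truth(noiseless_cohort_config, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
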