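"""Shared fixtures: small fast pipeline runs and a large register run.

The large run (100k initial persons) backs the statistical checks that need
Monte-Carlo headroom; it is generated once per session.  The small run
exercises mechanics only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from t2dms import reporting
from t2dms.config import PipelineConfig, RegisterConfig
from t2dms.synth_register import GroundTruthSchedule

SEED = 1


@pytest.fixture(scope="session")
def small_cfg() -> PipelineConfig:
    return PipelineConfig(seed=SEED, register=RegisterConfig(n_persons=4000))


@pytest.fixture(scope="session")
def small_run(small_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reporting.run_pipeline(small_cfg)


@pytest.fixture(scope="session")
def big_cfg() -> PipelineConfig:
    return PipelineConfig(seed=SEED, register=RegisterConfig(n_persons=100_000))


@pytest.fixture(scope="session")
def big_run(big_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reporting.run_pipeline(big_cfg)


@pytest.fixture(scope="session")
def true_schedule(big_cfg) -> GroundTruthSchedule:
    return GroundTruthSchedule(big_cfg.schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
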