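import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from telecopd.cohort import (CohortConfig, SYMPTOMS, generate_baseline,
                             generate_cohort, generate_daily)


@pytest.fixture(scope="session")
def tiny_config():
    return CohortConfig(n_patients=12, n_days=60, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    """Small simulated cohort shared across tests (baseline, records, truth)."""
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def clean_records():
    """A fully observed 4-patient cohort (no missingness)."""
    cfg = CohortConfig(n_patients=4, n_days=40, seed=3,
                       day_missing_prob=0.0, field_missing_prob=0.0)
    baseline = generate_baseline(cfg)
    records, truth = generate_daily(cfg, baseline)
    return baseline, records, truth


def make_day(present=()):
    """A single-day record with the named symptoms present, rest absent."""
    return {s: (1.0 if s in present else 0.0) for s in SYMPTOMS}


@pytest.fixture
def day_factory():
    return make_day
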