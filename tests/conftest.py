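import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from contactfatigue.data_model import RECORD_COLUMNS, build_design

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from contactfatigue.schema import CovariateSchema
from contactfatigue.synthetic import GeneratorConfig, generate_cohort

# fast MCMC settings for smoke-level fits; statistical quality is checked
# by the dedicated acceptance tests at larger sizes
FAST_MCMC = {"n_warmup": 300, "n_steps": 300, "n_walkers": None}


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a record frame from partial row dicts with sane defaults."""
    defaults = {
        "wave": 1, "part_id": "p0", "repeat_count": 0, "age": 30.0,
        "child_age_band": None, "attends_preschool": True, "sex": "male",
        "hh_size": "2", "employment": "full-time", "symptoms": "no",
        "day_type": "weekday", "urban_type": "urban", "y": 0, "date": 0,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows], columns=RECORD_COLUMNS)


@pytest.fixture(scope="session")
def schema():
    return CovariateSchema()


@pytest.fixture(scope="session")
def small_cohort():
    """Small multi-wave cohort with default (study-condition) truth."""
    cfg = GeneratorConfig(n_per_wave=250, n_waves=5, rng_seed=9)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_cohort, schema):
    _, rec = small_cohort
    return build_design(rec, schema)
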