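import numpy as np
import pytest

import sleepsca as ss
from sleepsca.measures import derive_measures


@pytest.fixture(scope="session")
def default_run():
    """Moderate default-configured cohort shared across test modules."""
    cfg = ss.default_config(4000, seed=42)
    cohort, diaries = ss.generate_cohort(cfg)
    derived = derive_measures(cohort, diaries)
    return cfg, cohort, diaries, derived


@pytest.fixture(scope="session")
def null_run():
    """Cohort with every injected effect zeroed."""
    cfg = ss.null_config(3000, seed=5)
    cohort, diaries = ss.generate_cohort(cfg)
    derived = derive_measures(cohort, diaries)
    return cfg, cohort, diaries, derived


@pytest.fixture(scope="session")
def small_run():
    """Small cohort with full diary coverage, for bootstrap-heavy tests."""
    cfg = ss.default_config(1500, seed=9, diary_fraction=1.0)
    cohort, diaries = ss.generate_cohort(cfg)
    derived = derive_measures(cohort, diaries)
    return cfg, cohort, diaries, derived
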