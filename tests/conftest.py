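import numpy as np
import pandas as pd
import pytest

from actiflm.design import TrialDesign
from actiflm.io import build_daily_profiles, classify_epochs, diary_from_frame
from actiflm.synthetic import (
    ActivityModel,
    CohortSpec,
    simulate_activity,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    spec = CohortSpec(n_subjects=6, n_female=4, n_male=2)
    return simulate_cohort(spec, seed=101)


@pytest.fixture(scope="session")
def small_design(small_cohort) -> TrialDesign:
    return TrialDesign.randomized(
        list(small_cohort["subject_id"]), seed=102, period_length=7, washout_length=3
    )


@pytest.fixture(scope="session")
def small_trial(small_cohort, small_design):
    """A compact simulated trial (6 subjects, 7-day periods) with the
    default treatment-effect windows, classified and profiled."""
    model = ActivityModel()
    series, diary = simulate_activity(small_cohort, small_design, model, seed=103)
    diaries = diary_from_frame(diary)
    labeled = [
        classify_epochs(series[sid], diaries[sid], small_design) for sid in series
    ]
    profiles = build_daily_profiles(labeled, grid_size=144)
    return {
        "cohort": small_cohort,
        "design": small_design,
        "model": model,
        "series": series,
        "diary": diary,
        "diaries": diaries,
        "labeled": labeled,
        "profiles": profiles,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
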