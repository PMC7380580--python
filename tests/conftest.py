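import numpy as np
import pandas as pd
import pytest

from fermomics import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One-time-point cohort, 30 subjects/group, 40 microbes."""
    cfg = SimulationConfig(n_subjects_per_group=30, n_timepoints=1,
                           n_microbes=40, n_metabolites=20, seed=11)
    table, meta, truth = simulate_cohort(cfg)
    return cfg, table, meta, truth


@pytest.fixture(scope="session")
def longitudinal_cohort():
    """Four weekly time points, 25 subjects/group."""
    cfg = SimulationConfig(n_subjects_per_group=25, n_timepoints=4,
                           n_microbes=60, n_metabolites=20, seed=21)
    table, meta, truth = simulate_cohort(cfg)
    return cfg, table, meta, truth


@pytest.fixture()
def toy_table():
    """3 samples x 4 features with known totals (feature d totals 4)."""
    return pd.DataFrame(
        [[10, 5, 3, 1], [8, 6, 0, 2], [12, 4, 5, 1]],
        index=["s1", "s2", "s3"], columns=["a", "b", "c", "d"],
    )


@pytest.fixture()
def participant_meta():
    """Hand-constructed metadata rows exercising every exclusion rule."""
    rows = {
        "ok":        dict(age=35, bmi=24.0, height_cm=170, weight_kg=70, antibiotic_past_year="No"),
        "age_low":   dict(age=18, bmi=24.0, height_cm=170, weight_kg=70, antibiotic_past_year="No"),
        "age_19":    dict(age=19, bmi=24.0, height_cm=170, weight_kg=70, antibiotic_past_year="No"),
        "age_high":  dict(age=70, bmi=24.0, height_cm=170, weight_kg=70, antibiotic_past_year="No"),
        "bmi_high":  dict(age=35, bmi=55.0, height_cm=170, weight_kg=70, antibiotic_past_year="No"),
        "bmi_low":   dict(age=35, bmi=14.0, height_cm=170, weight_kg=70, antibiotic_past_year="No"),
        "short":     dict(age=35, bmi=24.0, height_cm=47, weight_kg=70, antibiotic_past_year="No"),
        "tall":      dict(age=35, bmi=24.0, height_cm=211, weight_kg=70, antibiotic_past_year="No"),
        "heavy":     dict(age=35, bmi=24.0, height_cm=170, weight_kg=201, antibiotic_past_year="No"),
        "light":     dict(age=35, bmi=24.0, height_cm=170, weight_kg=2.0, antibiotic_past_year="No"),
        "abx":       dict(age=35, bmi=24.0, height_cm=170, weight_kg=70, antibiotic_past_year="Yes"),
        "missing":   dict(age=np.nan, bmi=24.0, height_cm=170, weight_kg=70, antibiotic_past_year="No"),
    }
    return pd.DataFrame.from_dict(rows, orient="index")
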