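import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated matched cohort with planted effects."""
    import comorbscreen as cs

    design = cs.SimulationDesign(n_pairs=400, m_codes=60, pi1=0.2,
                                 log_or=np.log(3.0),
                                 prevalence_range=(0.05, 0.15), seed=42)
    cohort, truth = cs.simulate_cohort(design)
    return cohort, truth


@pytest.fixture()
def demo_profiles():
    """Hand-built case/control profiles spanning two exact strata."""
    rows = [
        # patient_id, cohort, sex, age, quintile, rurality, index_date
        ("c1", "case", "F", 30.0, 3, "urban", "2015-06-01"),
        ("c2", "case", "F", 31.0, 3, "urban", "2015-06-01"),
        ("c3", "case", "M", 50.0, 1, "rural", "2015-06-01"),
        ("k1", "control", "F", 29.0, 3, "urban", "2015-05-01"),
        ("k2", "control", "F", 35.0, 3, "urban", "2015-05-01"),
        ("k3", "control", "M", 49.5, 1, "rural", "2015-05-01"),
        ("k4", "control", "M", 80.0, 1, "rural", "2015-05-01"),
    ]
    return pd.DataFrame(rows, columns=[
        "patient_id", "cohort", "sex", "age_years", "income_quintile",
        "rurality", "index_date"])
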