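import numpy as np
import pandas as pd
import pytest

from romtraj import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient simulated cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(n_atsa=30, n_rtsa=30, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_visits(rows):
    """Build a visit frame from (patient_id, time, is_preop, measure, value) tuples."""
    return pd.DataFrame(
        rows, columns=["patient_id", "time_months", "is_preop", "measure", "value"])


def make_patient(pid="P1", prosthesis="aTSA", **overrides):
    """A minimal valid patient row as a dict."""
    row = {
        "patient_id": pid, "prosthesis": prosthesis, "age_years": 65.0,
        "sex": "F", "bmi": 29.0, "previous_surgery": 0, "injections": 0,
        "dx_osteoarthritis": 1, "dx_osteonecrosis": 0, "dx_rotator_cuff_tear": 0,
        "dx_cuff_tear_arthropathy": 0, "dx_rheumatoid_arthritis": 0,
        "cm_none": 1, "cm_hypertension": 0, "cm_heart_disease": 0,
        "cm_diabetes": 0, "cm_tobacco": 0, "cm_renal_failure": 0,
        "humeral_rll": 0, "glenoid_rll": 0, "glenoid_rll_grade": 0,
        "scapular_notching": 0, "notching_grade": 0,
        "complication": 0, "revision": 0, "revision_time_months": np.nan,
    }
    row.update(overrides)
    return row


def make_patients(rows):
    return pd.DataFrame(rows)
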