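import numpy as np
import pytest

from toponet.model import ModelConfig, TachycardiaOnsetModel
from toponet.sampling import SamplingConfig, balance_and_split, build_samples
from toponet.simulate import CohortParams, ProdromeSpec, generate_cohort
from toponet.vitals import StaticProfile, VitalChannel, PatientRecord


@pytest.fixture
def icu_profile():
    return StaticProfile(66.0, "female", "emergency", "medical-ICU", True)


@pytest.fixture
def ward_profile():
    return StaticProfile(61.0, "male", "elective", None, True)


def make_record(hr, rr=None, spo2=None, profile=None, pid="P0"):
    hr = np.asarray(hr, dtype=float)
    rr = np.full_like(hr, 16.0) if rr is None else np.asarray(rr, dtype=float)
    spo2 = np.full_like(hr, 97.0) if spo2 is None else np.asarray(spo2, dtype=float)
    profile = profile or StaticProfile(66.0, "female", "emergency", "medical-ICU", True)
    return PatientRecord(
        pid,
        {"hr": VitalChannel("hr", hr), "rr": VitalChannel("rr", rr),
         "spo2": VitalChannel("spo2", spo2)},
        profile,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """40-patient prodrome cohort with exact ground truth, seeded."""
    params = CohortParams(n_patients=40, prevalence=0.5, seed=11)
    records, truth = generate_cohort(params, ProdromeSpec(), seed=11)
    return records, truth


@pytest.fixture(scope="session")
def trained(small_cohort):
    """A fitted model plus its train/test split (2-hour forecast range)."""
    records, _ = small_cohort
    samples = build_samples(records, SamplingConfig(forecast_range=2))
    train, test = balance_and_split(samples, seed=11)
    results = TachycardiaOnsetModel(train).fit(ModelConfig(seed=11))
    return results, train, test
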