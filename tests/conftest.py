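import numpy as np
import pytest

from epigram.pipeline import run_patient_study
from epigram.synthetic_eeg import generate_recording, patient_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synthetic_patient():
    """One canonical prediction-regime patient (seed 0)."""
    return generate_recording(patient_config(0))


@pytest.fixture(scope="session")
def patient_study(synthetic_patient):
    """Full prediction study on the canonical patient, shared by tests."""
    recording, annotations = synthetic_patient
    result = run_patient_study(
        recording, annotations, mode="prediction", sop_min=10.0, seed=0
    )
    return recording, annotations, result
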