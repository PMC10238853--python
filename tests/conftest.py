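import numpy as np
import pytest

from procrmb import (
    CLINICIAN,
    PATIENT,
    CalibrationParams,
    EndpointSpec,
    calibrate_skeleton,
    default_config,
)


@pytest.fixture(scope="session")
def clinician_spec() -> EndpointSpec:
    skeleton = calibrate_skeleton(0.20, CalibrationParams(halfwidth=0.05), 2)
    return EndpointSpec(CLINICIAN, target=0.20, skeleton=skeleton, prior_sd=np.sqrt(1.60))


@pytest.fixture(scope="session")
def patient_spec() -> EndpointSpec:
    skeleton = calibrate_skeleton(0.55, CalibrationParams(halfwidth=0.05), 2)
    return EndpointSpec(PATIENT, target=0.55, skeleton=skeleton, prior_sd=np.sqrt(1.58))


@pytest.fixture(scope="session")
def design_config():
    return default_config()


#: Per-cohort (c_dlt, p_dlt) outcomes of the reference sequential trial used
#: throughout the tests: dose path 1 -> 2 -> 1 -> 2 -> 2, final MTD level 2.
WORKED_TRIAL_COHORTS = [
    [(0, 1), (0, 0), (0, 0)],  # cohort 1 at level 1: 0 C-DLT, 1 P-DLT
    [(1, 1), (0, 1), (0, 0)],  # cohort 2 at level 2: 1 C-DLT, 2 P-DLT
    [(0, 0), (0, 0), (0, 0)],  # cohort 3 at level 1: none
    [(1, 0), (0, 0), (0, 0)],  # cohort 4 at level 2: 1 C-DLT
    [(0, 1), (0, 0), (0, 0)],  # cohort 5 at level 2: 1 P-DLT
]


@pytest.fixture(scope="session")
def worked_trial_cohorts():
    return [list(cohort) for cohort in WORKED_TRIAL_COHORTS]
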