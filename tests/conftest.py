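import numpy as np
import pandas as pd
import pytest

from anxiomark.cohort import ExpressionMatrix, VisitRecord
from anxiomark.simulate import SimulationConfig, simulate_cohort


def make_record(sample_id="S1", subject_id="P1", visit_index=1, gender="M",
                diagnosis="BP", sas4=50.0, **kwargs) -> VisitRecord:
    return VisitRecord(sample_id=sample_id, subject_id=subject_id,
                       visit_index=visit_index, gender=gender,
                       diagnosis=diagnosis, sas4=sas4, **kwargs)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_subjects_discovery=16, n_subjects_validation=10, n_subjects_test=30,
        n_probesets=120, n_state_markers=6, n_trait_markers=6, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def toy_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0], [0.5, 1.5, 2.5, 3.5]],
        index=["p1", "p2", "p3"], columns=["S1", "S2", "S3", "S4"])
    return ExpressionMatrix(values)


@pytest.fixture()
def toy_records() -> list[VisitRecord]:
    return [
        make_record("S1", "A", 1, "M", "BP", sas4=20.0),
        make_record("S2", "A", 2, "M", "BP", sas4=70.0),
        make_record("S3", "B", 1, "F", "MDD", sas4=30.0),
        make_record("S4", "B", 2, "F", "MDD", sas4=80.0),
    ]
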