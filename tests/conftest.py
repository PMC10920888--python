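from datetime import date

import pandas as pd
import pytest

from comotraj.records import CohortConfig, HospitalStay


def make_stay(pid="P1", sex="male", age=45, adm="2005-03-01", rel="2005-03-04",
              rtype="discharge", codes=("I10",)):
    return HospitalStay(
        patient_id=pid, sex=sex, age_band=age,
        admission_date=date.fromisoformat(adm),
        release_date=date.fromisoformat(rel),
        release_type=rtype, diagnoses=tuple(codes),
    )


@pytest.fixture
def cohort_cfg():
    return CohortConfig()


@pytest.fixture
def stays_csv(tmp_path):
    """Three valid stays in the canonical CSV dialect."""
    path = tmp_path / "stays.csv"
    pd.DataFrame([
        {"patient_id": "P1", "sex": "male", "age": 45,
         "admission_date": "2005-03-01", "release_date": "2005-03-04",
         "release_type": "discharge", "diagnoses": "I10;E66"},
        {"patient_id": "P2", "sex": "female", "age": 20,
         "admission_date": "2007-06-10", "release_date": "2007-06-10",
         "release_type": "discharge", "diagnoses": "G47"},
        {"patient_id": "P1", "sex": "male", "age": 50,
         "admission_date": "2010-01-05", "release_date": "2010-01-20",
         "release_type": "death", "diagnoses": "I10;N18;J18"},
    ]).to_csv(path, index=False)
    return path
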