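from datetime import date, timedelta

import pytest

from losnet import make_fixture
from losnet.eci import default_eci_mapping
from losnet.records import AdmissionRecord


@pytest.fixture(scope="session")
def tiny_cohort():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def small_cohort():
    return make_fixture("small")


@pytest.fixture(scope="session")
def eci_map():
    return default_eci_mapping()


def make_record(
    record_id="R1",
    patient_id="P1",
    sex="female",
    age=72,
    admission=date(2018, 6, 1),
    los=10,
    diagnoses=(("I10", True),),
    **kw,
):
    """Hand-built admission record with sensible defaults."""
    defaults = dict(
        ethnic_group="han",
        hospital_id="H1",
        hospital_level=3,
        hospital_grade=1,
        hospital_affiliation=1,
        hospital_address_code=5,
        patient_address_code=5,
        admission_status=3,
        admission_source=2,
        job=4,
        marital_status=2,
    )
    defaults.update(kw)
    return AdmissionRecord(
        record_id=record_id,
        patient_id=patient_id,
        sex=sex,
        age=age,
        admission_date=admission,
        discharge_date=admission + timedelta(days=los),
        los=los,
        diagnoses=tuple(diagnoses),
        **defaults,
    )
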