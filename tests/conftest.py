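from datetime import date, timedelta

import pytest
from hypothesis import settings

from cedlar import (
    ExamRecord,
    Modality,
    PatientHistory,
    Protocol,
    expand_fixture_history,
    load_table2_patients,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_ct(pid="P1", day=0, dose=1.0, origin=date(2021, 1, 1),
            protocol=Protocol.OTHER, modality=Modality.CT, dlp=None):
    return ExamRecord(
        patient_id=pid,
        study_date=origin + timedelta(days=day),
        modality=modality,
        protocol=protocol,
        effective_dose_mSv=dose,
        dlp_mGycm=dlp,
    )


def history_from_days(days_doses, pid="P1", **kw):
    return PatientHistory(
        [make_ct(pid=pid, day=d, dose=x, **kw) for d, x in days_doses]
    )


@pytest.fixture(scope="session")
def fixture_entries():
    return load_table2_patients()


@pytest.fixture(scope="session")
def expanded_histories(fixture_entries):
    return [expand_fixture_history(e) for e in fixture_entries]
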