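import pandas as pd
import pytest

from traitphewas.synthetic import toy_terminology


@pytest.fixture(scope="session")
def block_terminology():
    """Block-scheme terminology over the packaged toy hierarchy (62 blocks)."""
    return toy_terminology()


@pytest.fixture()
def tiny_cohort_frames():
    """Hand-written 4-patient cohort exercising every table."""
    patients = pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3", "p4"],
            "sex": ["female", "male", "female", "male"],
            "birth_year": [1970, 1955, 1980, 1960],
        }
    )
    assays = pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3", "p4", "p4"],
            "date": pd.to_datetime(
                ["2003-01-01", "2003-02-01", "2003-03-01", "2003-01-01",
                 "2004-01-01"]
            ),
            "activity": [17.0, 12.0, 6.0, 14.9, 15.2],
        }
    )
    encounters = pd.DataFrame(
        {
            "encounter_id": ["e1", "e2", "e3"],
            "patient_id": ["p1", "p1", "p2"],
            "type": ["hospitalization", "consultation", "session"],
            "start_date": pd.to_datetime(["2004-01-10", "2004-02-10", "2004-03-01"]),
            "end_date": pd.to_datetime(["2004-01-12", "2004-02-10", "2004-03-01"]),
        }
    )
    diagnoses = pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2", "p3", "p4"],
            "encounter_id": ["e1", "e2", "e3", "", ""],
            "date": pd.to_datetime(
                ["2004-01-10", "2004-02-10", "2004-03-01", "2004-05-01",
                 "2002-01-01"]
            ),
            "code": ["C18", "K50.1", "D12", "K500", "E11"],
        }
    )
    labs = pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2", "p3"],
            "encounter_id": ["e1", "e2", "e3", ""],
            "date": pd.to_datetime(
                ["2004-01-10", "2004-02-10", "2004-03-01", "2004-06-01"]
            ),
            "test_id": ["hemoglobin", "hemoglobin", "hemoglobin", "glycemia"],
            "value": [8.5, 12.0, 13.0, 1.5],
        }
    )
    mentions = pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3", "p4"],
            "date": pd.to_datetime(
                ["2004-01-01", "2004-02-01", "2004-04-01", "2001-06-01"]
            ),
            "source": ["report", "cpoe", "report", "report"],
            "payload": [
                "mise sous Imurel 100mg",
                "AZATHIOPRINE 50mg",
                "traitement par mercaptopurine",
                "paracétamol seul",
            ],
        }
    )
    return dict(
        patients=patients, assays=assays, encounters=encounters,
        diagnoses=diagnoses, labs=labs, mentions=mentions,
    )
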