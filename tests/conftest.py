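import datetime as dt

import pytest

from spoorstats.survey_data import (
    SpoorRecord,
    Stratum,
    SurveyDataset,
    Transect,
    svc2008_survey,
)

DAY = dt.date(2008, 10, 1)


def record(species="lion", transect_id="T1", position_km=1.0, group_size=1,
           recorded_on=DAY, lut="private", age_hours=None, duplicate_of=None,
           record_id=None):
    return SpoorRecord(species, transect_id, position_km, group_size,
                       recorded_on, lut, age_hours, duplicate_of, record_id)


@pytest.fixture
def tiny_dataset():
    """3 records on 2 transects across 2 strata."""
    transects = [Transect("T1", "private", 10.0, 1), Transect("T2", "communal", 5.0, 1)]
    strata = [Stratum("private", 100.0), Stratum("communal", 50.0)]
    records = [
        record("lion", "T1", 2.0, record_id="a"),
        record("lion", "T1", 7.5, record_id="b"),
        record("leopard", "T2", 1.0, lut="communal", record_id="c"),
    ]
    return SurveyDataset(records=records, transects=transects, strata=strata)


@pytest.fixture(scope="session")
def svc():
    """The packaged worked-example survey (deterministic)."""
    return svc2008_survey()
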