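import datetime as dt

import hypothesis.strategies as st
import pytest
from hypothesis import given, settings

from spoorstats.survey_data import (
    SVC2008_COUNTS,
    SpoorRecord,
    Stratum,
    SurveyDataset,
    SurveyFormatError,
    SurveyReferenceError,
    Transect,
    read_survey,
    svc2008_survey,
    validate,
    write_survey,
)

from conftest import record


class TestReadWrite:
    def test_round_trip_identity(self, tiny_dataset, tmp_path):
        write_survey(tiny_dataset, tmp_path)
        again = read_survey(tmp_path)
        assert again.records == tiny_dataset.records
        assert again.transects == tiny_dataset.transects
        assert again.strata == tiny_dataset.strata

    def test_tiny_fixture_shape(self, tiny_dataset, tmp_path):
        write_survey(tiny_dataset, tmp_path)
        dataset = read_survey(tmp_path)
        assert len(dataset.records) == 3
        assert len(dataset.transects) == 2

    def test_tab_delimited_accepted(self, tiny_dataset, tmp_path):
        write_survey(tiny_dataset, tmp_path, sep="\t")
        assert read_survey(tmp_path).records == tiny_dataset.records

    def test_empty_dataset_writes_header_only(self, tmp_path):
        write_survey(SurveyDataset(), tmp_path)
        lines = (tmp_path / "records.csv").read_text().strip().splitlines()
        assert len(lines) == 1  # header only
        assert read_survey(tmp_path).records == []

    def test_missing_column_named_in_error(self, tiny_dataset, tmp_path):
        write_survey(tiny_dataset, tmp_path)
        path = tmp_path / "records.csv"
        lines = path.read_text().splitlines()
        lines[0] = lines[0].replace("species", "sp")
        path.write_text("\n".join(lines))
        with pytest.raises(SurveyFormatError, match="species"):
            read_survey(tmp_path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(SurveyFormatError, match="not found"):
            read_survey(tmp_path)

    def test_unknown_transect_is_reference_error(self, tiny_dataset, tmp_path):
        bad = SurveyDataset(
            records=[record(transect_id="NOPE")],
            transects=tiny_dataset.transects,
            strata=tiny_dataset.strata,
        )
        write_survey(bad, tmp_path)
        with pytest.raises(SurveyReferenceError, match="NOPE"):
            read_survey(tmp_path)

    def test_position_beyond_transect_is_reference_error(self, tiny_dataset, tmp_path):
        bad = SurveyDataset(
            records=[record(transect_id="T1", position_km=12.0)],
            transects=tiny_dataset.transects,  # T1 is 10 km
            strata=tiny_dataset.strata,
        )
        write_survey(bad, tmp_path)
        with pytest.raises(SurveyReferenceError, match="position"):
            read_survey(tmp_path)

    def test_round_trip_of_simulated_dataset(self, tmp_path):
        from spoorstats.synthetic_survey import make_svc_scenario, simulate_survey

        dataset = simulate_survey(make_svc_scenario(), seed=1)
        write_survey(dataset, tmp_path)
        assert read_survey(tmp_path).records == dataset.records


class TestValidate:
    def test_valid_fixture_is_clean(self, tiny_dataset):
        assert validate(tiny_dataset) == []

    def test_validate_is_pure(self, tiny_dataset):
        assert validate(tiny_dataset) == validate(tiny_dataset)

    def test_group_size_zero(self, tiny_dataset):
        tiny_dataset.records.append(record(group_size=0, record_id="z"))
        bad = [v for v in validate(tiny_dataset) if v.rule == "group_size_ge_1"]
        assert len(bad) == 1

    def test_duplicate_transect_ids(self, tiny_dataset):
        tiny_dataset.transects.append(Transect("T1", "private", 3.0, 1))
        bad = [v for v in validate(tiny_dataset) if v.rule == "unique_id"]
        assert len(bad) == 1

    def test_duplicate_of_must_match_context(self, tiny_dataset):
        tiny_dataset.records.append(
            record("leopard", "T1", 3.0, duplicate_of="a", record_id="d")
        )  # record "a" is a lion
        rules = {v.rule for v in validate(tiny_dataset)}
        assert "duplicate_same_context" in rules

    def test_duplicate_of_must_be_earlier(self, tiny_dataset):
        tiny_dataset.records.insert(
            0, record("lion", "T1", 3.0, duplicate_of="a", record_id="d")
        )
        rules = {v.rule for v in validate(tiny_dataset)}
        assert "duplicate_earlier" in rules

    def test_transect_without_stratum(self, tiny_dataset):
        tiny_dataset.transects.append(Transect("T9", "resettlement", 3.0, 1))
        rules = {v.rule for v in validate(tiny_dataset)}
        assert "stratum_exists" in rules


class TestSvc2008Fixture:
    def test_per_species_totals_match_published_counts(self, svc):
        for (species, lut), count in SVC2008_COUNTS.items():
            got = sum(1 for r in svc.records if r.species == species and r.lut == lut)
            assert got == count

    def test_total_spoor(self, svc):
        assert len(svc.records) == 65 + 101 + 10 + 129 + 12 + 106

    def test_only_spotted_hyaena_outside_private(self, svc):
        outside = {r.species for r in svc.records if r.lut != "private"}
        assert outside == {"spotted_hyaena"}
        assert not any(r.lut == "communal" for r in svc.records)

    def test_fixture_is_valid_and_deterministic(self, svc):
        assert validate(svc) == []
        assert svc2008_survey().records == svc.records


# --- property: read/write round-trip on generated datasets -----------------

_species = st.sampled_from(["lion", "leopard", "cheetah", "caracal"])
_luts = st.sampled_from(["private", "resettlement", "communal"])


@st.composite
def datasets(draw):
    n_transects = draw(st.integers(1, 3))
    transects = []
    for i in range(n_transects):
        transects.append(
            Transect(
                f"T{i}",
                draw(_luts),
                float(draw(st.integers(1, 50))),
                draw(st.integers(1, 3)),
            )
        )
    strata = [Stratum(lut, 100.0) for lut in {t.lut for t in transects}]
    n_records = draw(st.integers(0, 8))
    records = []
    for j in range(n_records):
        t = transects[draw(st.integers(0, n_transects - 1))]
        frac = draw(st.floats(0.0, 1.0, allow_nan=False))
        records.append(
            SpoorRecord(
                species=draw(_species),
                transect_id=t.transect_id,
                position_km=frac * t.length_km,
                group_size=draw(st.integers(1, 5)),
                recorded_on=dt.date(2008, 10, 1) + dt.timedelta(days=draw(st.integers(0, t.passes - 1))),
                lut=t.lut,
                age_hours=draw(st.one_of(st.none(), st.floats(0.0, 100.0, allow_nan=False))),
                record_id=f"r{j}",
            )
        )
    return SurveyDataset(records=records, transects=transects, strata=strata)


@settings(max_examples=40, deadline=None)
@given(datasets())
def test_round_trip_property(tmp_path_factory, dataset):
    tmp = tmp_path_factory.mktemp("rt")
    write_survey(dataset, tmp)
    again = read_survey(tmp)
    assert again.records == dataset.records
    assert again.transects == dataset.transects
    assert again.strata == dataset.strata
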