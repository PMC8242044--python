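"""Survey schema: CSV round-trip, validation totality, eligibility rules."""

from __future__ import annotations

import csv

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flockrate.records import (
    COLUMNS,
    DEATH_CAUSES,
    INTAKE_CAUSES,
    OFFTAKE_CAUSES,
    FlockSurveyRecord,
    FlowTallies,
    ReproductionTallies,
    SchemaError,
    SpeciesRecord,
    SpeciesStructure,
    classify_pastoralist,
    fei_eligible,
    read_survey_csv,
    species_eligible,
    write_survey_csv,
)

from conftest import make_eligible_flock, make_species_record


def _write_rows(path, rows):
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def _base_row(flock_id="f1", species="sheep", **overrides):
    row = {c: 0 for c in COLUMNS}
    row.update(
        flock_id=flock_id,
        ward="w",
        species=species,
        usually_buys_animals="false",
        removing_goats="false",
        adverse_events="",
        young_females=5,
        young_males=5,
        repro_females=8,
        older_males=2,
        age_first_parturition="",
        age_at_replacement="",
    )
    row.update(overrides)
    return row


class TestReadValidate:
    def test_well_formed_rows_all_accepted(self, tmp_path):
        path = tmp_path / "survey.csv"
        _write_rows(
            path,
            [_base_row("f1"), _base_row("f2", species="goat"), _base_row("f3")],
        )
        result = read_survey_csv(path)
        assert len(result.records) == 3
        assert result.rejects == []

    def test_negative_count_rejected_with_field_name(self, tmp_path):
        path = tmp_path / "survey.csv"
        _write_rows(
            path,
            [_base_row("f1"), _base_row("f2", deaths_disease=-1), _base_row("f3")],
        )
        result = read_survey_csv(path)
        assert len(result.records) == 2
        assert len(result.rejects) == 1
        issue = result.rejects[0]
        assert issue.field == "deaths_disease"
        assert issue.flock_id == "f2"

    def test_negative_start_size_rejected(self, tmp_path):
        # 20 animals now, 30 intakes, no exits -> start would be -10
        path = tmp_path / "survey.csv"
        _write_rows(path, [_base_row("f1", intakes_purchase=30)])
        result = read_survey_csv(path)
        assert result.records == []
        assert len(result.rejects) == 1
        assert "start size" in result.rejects[0].reason

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        path = tmp_path / "survey.csv"
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow([c for c in COLUMNS if c != "deaths_disease"])
        with pytest.raises(SchemaError, match="deaths_disease"):
            read_survey_csv(path)

    def test_every_row_accepted_or_rejected(self, tmp_path):
        rows = [
            _base_row("f1"),
            _base_row("f2", deaths_disease=-3),
            _base_row("", species="sheep"),
            _base_row("f4", species="camel"),
            _base_row("f5", intakes_purchase=999),
        ]
        path = tmp_path / "survey.csv"
        _write_rows(path, rows)
        result = read_survey_csv(path)
        n_species_rows = sum(len(r.species_records()) for r in result.records)
        assert n_species_rows + len(result.rejects) == len(rows)

    def test_multi_flock_rows_are_pooled(self, tmp_path):
        path = tmp_path / "survey.csv"
        _write_rows(
            path,
            [
                _base_row("f1", births_alive=3, offspring_alive=3, deaths_disease=1),
                _base_row("f1", births_alive=2, offspring_alive=2, deaths_disease=4),
            ],
        )
        result = read_survey_csv(path)
        assert len(result.records) == 1
        rec = result.records[0].sheep
        assert rec.flows.births_alive == 5
        assert rec.flows.deaths_by_cause["disease"] == 5
        assert rec.structure.total() == 40  # counts summed across sub-flocks

    def test_mismatched_births_is_warning_not_reject(self, tmp_path):
        path = tmp_path / "survey.csv"
        _write_rows(path, [_base_row("f1", births_alive=4, offspring_alive=6)])
        result = read_survey_csv(path)
        assert len(result.records) == 1
        assert any("births_alive" in w for w in result.warnings)


class TestRoundTrip:
    def test_empty_cohort_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_survey_csv([], path)
        assert path.read_text().strip() == ",".join(COLUMNS)
        assert read_survey_csv(path).records == []

    def test_all_zero_flows_round_trip(self, tmp_path):
        record = make_eligible_flock("f1")
        path = tmp_path / "one.csv"
        write_survey_csv([record], path)
        result = read_survey_csv(path)
        assert result.rejects == []
        assert result.records == [record]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_round_trip_lossless_for_random_cohorts(self, tmp_path_factory, data):
        records = data.draw(
            st.lists(_record_strategy(), min_size=1, max_size=6, unique_by=lambda r: r.flock_id)
        )
        path = tmp_path_factory.mktemp("rt") / "survey.csv"
        write_survey_csv(records, path)
        result = read_survey_csv(path)
        assert result.rejects == []
        assert result.records == records


def _species_record_strategy(species):
    counts = st.integers(min_value=0, max_value=30)
    structure = st.builds(SpeciesStructure, counts, counts, counts, counts)
    repro = st.builds(
        ReproductionTallies,
        parturitions_single=st.integers(0, 20),
        parturitions_twin=st.integers(0, 5),
        parturitions_triplet=st.integers(0, 2),
        offspring_alive=st.integers(0, 30),
        offspring_stillborn=st.integers(0, 4),
        abortions=st.integers(0, 4),
        dystocias=st.integers(0, 0),
        reported_age_first_parturition=st.one_of(
            st.none(), st.floats(1.0, 4.0, allow_nan=False)
        ),
        reported_age_at_replacement=st.one_of(
            st.none(), st.floats(4.0, 10.0, allow_nan=False)
        ),
    )
    flows = st.builds(
        FlowTallies,
        births_alive=st.integers(0, 10),
        deaths_by_cause=st.fixed_dictionaries({c: st.integers(0, 5) for c in DEATH_CAUSES}),
        offtakes_by_cause=st.fixed_dictionaries(
            {c: st.integers(0, 5) for c in OFFTAKE_CAUSES}
        ),
        intakes_by_cause=st.fixed_dictionaries(
            {c: st.integers(0, 3) for c in INTAKE_CAUSES}
        ),
    )
    return (
        st.builds(
            SpeciesRecord,
            species=st.just(species),
            structure=structure,
            reproduction=repro,
            flows=flows,
        )
        .filter(lambda r: not r.validation_errors())
    )


def _record_strategy():
    ids = st.text(alphabet="abcdefgh123", min_size=1, max_size=8)
    return st.builds(
        FlockSurveyRecord,
        flock_id=ids,
        ward=st.sampled_from(["", "kaputiei_north", "ildamat"]),
        usually_buys_animals=st.one_of(st.none(), st.booleans()),
        removing_goats=st.booleans(),
        sheep=st.one_of(st.none(), _species_record_strategy("sheep")),
        goats=_species_record_strategy("goat"),
        adverse_events=st.frozensets(
            st.sampled_from(["disease", "drought", "predation"]), max_size=3
        ),
    )


class TestClassification:
    @pytest.mark.parametrize(
        "flag,expected",
        [
            (True, "pastoralist_and_trader"),
            (False, "pastoralist_only"),
            (None, "unknown"),
        ],
    )
    def test_classify_pastoralist(self, flag, expected):
        record = make_eligible_flock("f1", usually_buys_animals=flag)
        assert classify_pastoralist(record) == expected


class TestEligibility:
    @pytest.mark.parametrize(
        "species,total,removing,expected",
        [
            ("goat", 35, False, True),
            ("goat", 35, True, False),
            ("sheep", 35, True, True),  # goat removal does not affect sheep
            ("sheep", 9, False, False),
            ("sheep", 10, False, True),
        ],
    )
    def test_species_eligible(self, species, total, removing, expected):
        rec = make_species_record(species, total)
        assert species_eligible(rec, removing_goats=removing) is expected

    @pytest.mark.parametrize(
        "n_sheep,n_goats,removing,expected",
        [
            (20, 15, False, True),
            (20, 9, False, False),  # under 10 of one species
            (15, 12, False, False),  # combined under 30
            (20, 15, True, False),  # removing goats
        ],
    )
    def test_fei_eligible(self, n_sheep, n_goats, removing, expected):
        record = make_eligible_flock(
            "f1", n_sheep=n_sheep, n_goats=n_goats, removing_goats=removing
        )
        assert fei_eligible(record) is expected

    def test_fei_requires_both_species(self):
        record = FlockSurveyRecord(flock_id="f1", sheep=make_species_record("sheep", 40))
        assert fei_eligible(record) is False
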