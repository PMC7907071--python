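"""Cohort data model: I/O round-trips, recoding and descriptive summaries."""

import tempfile
from pathlib import Path

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from addinter import (
    DomainError,
    FormatError,
    SubjectRecord,
    ValidationError,
    default_codebook,
    dichotomize,
    read_cohort,
    summarize_cohort,
    write_cohort,
)

from conftest import make_record

CODEBOOK = default_codebook()
EXPOSURE_VARS = [v for v in CODEBOOK.data_columns() if v != "sex"]


def write_csv(path, text):
    Path(path).write_text(text, encoding="utf-8")


class TestReadCohort:
    HEADER = "subject_id,pair_id,case,sex,age," + ",".join(EXPOSURE_VARS)

    def row(self, sid, case, drinking="no"):
        values = {v: "" for v in EXPOSURE_VARS}
        values.update(
            family_history="yes", diabetes="no", drinking=drinking,
            taste="salty", smoking="no", sports="regular", pressure="none",
        )
        return f"{sid},,{case},male,50," + ",".join(values[v] for v in EXPOSURE_VARS)

    def test_reads_declared_rows(self, tmp_path):
        path = tmp_path / "cohort.csv"
        rows = [self.row(f"s{i}", i % 2) for i in range(4)]
        write_csv(path, "\n".join([self.HEADER] + rows) + "\n")
        records = read_cohort(path, CODEBOOK)
        assert len(records) == 4
        assert records[0].exposures["family_history"] == "yes"
        assert all(r.exposures["drinking"] == "no" for r in records)

    def test_undeclared_level_names_variable_and_row(self, tmp_path):
        path = tmp_path / "cohort.csv"
        write_csv(path, "\n".join([self.HEADER, self.row("s1", 1, drinking="sometimes")]) + "\n")
        with pytest.raises(ValidationError, match="drinking"):
            read_cohort(path, CODEBOOK)

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "cohort.csv"
        write_csv(path, "subject_id,case,sex,age\ns1,1,male,50\n")
        with pytest.raises(FormatError, match="missing mandatory column"):
            read_cohort(path, CODEBOOK)

    def test_duplicate_subject_id_rejected(self, tmp_path):
        path = tmp_path / "cohort.csv"
        write_csv(path, "\n".join([self.HEADER, self.row("s1", 1), self.row("s1", 0)]) + "\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_cohort(path, CODEBOOK)


level_strategy = {
    var: st.one_of(st.none(), st.sampled_from(CODEBOOK[var].levels))
    for var in EXPOSURE_VARS
}


@st.composite
def cohorts(draw):
    n = draw(st.integers(min_value=1, max_value=20))
    records = []
    for i in range(n):
        exposures = {var: draw(level_strategy[var]) for var in EXPOSURE_VARS}
        records.append(
            SubjectRecord(
                subject_id=f"s{i}",
                is_case=draw(st.booleans()),
                sex=draw(st.sampled_from(("male", "female"))),
                age=draw(st.integers(min_value=0, max_value=99)),
                pair_id=draw(st.one_of(st.none(), st.just(f"P{i}"))),
                exposures=exposures,
            )
        )
    return records


@given(records=cohorts())
@settings(max_examples=40, deadline=None, derandomize=True,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
def test_write_read_round_trip_preserves_every_field(records):
    """Writing then re-reading any valid cohort reproduces it record for record."""
    with tempfile.TemporaryDirectory() as tmp:
        path = Path(tmp) / "cohort.csv"
        write_cohort(records, path, CODEBOOK)
        recovered = read_cohort(path, CODEBOOK)
    assert recovered == records


class TestDichotomize:
    @pytest.mark.parametrize(
        "variable,level,expected",
        [
            ("drinking", "occasionally", "1"),
            ("drinking", "regular", "1"),
            ("drinking", "no", "0"),
            ("taste", "balance", "0"),
            ("taste", "light", "0"),
            ("taste", "salty", "1"),
            ("pressure", "little", "1"),
            ("pressure", "none", "0"),
        ],
    )
    def test_study_recodes(self, variable, level, expected):
        records = [make_record("s0", True, **{variable: level})]
        out = dichotomize(records, variable, CODEBOOK)
        assert out[0].exposures[variable] == expected

    def test_other_fields_unchanged(self):
        rec = make_record("s0", True, drinking="regular", taste="salty")
        out = dichotomize([rec], "drinking", CODEBOOK)[0]
        assert out.subject_id == rec.subject_id
        assert out.exposures["taste"] == "salty"

    def test_idempotent_on_own_output(self):
        records = [make_record(f"s{i}", True, drinking=lv)
                   for i, lv in enumerate(("no", "occasionally", "regular"))]
        once = dichotomize(records, "drinking", CODEBOOK)
        twice = dichotomize(once, "drinking", CODEBOOK)
        assert once == twice

    def test_identity_map_preserves_binary_variable(self):
        records = [make_record("s0", True, family_history="yes")]
        once = dichotomize(records, "family_history", CODEBOOK)
        assert dichotomize(once, "family_history", CODEBOOK) == once

    def test_missing_values_stay_missing(self):
        out = dichotomize([make_record("s0", True, drinking=None)], "drinking", CODEBOOK)
        assert out[0].exposures["drinking"] is None

    def test_absent_variable_is_lookup_error(self):
        with pytest.raises(KeyError):
            dichotomize([make_record("s0", True)], "bmi", CODEBOOK)


class TestSummarize:
    def test_case_control_totals(self):
        records = [make_record(f"c{i}", True) for i in range(342)]
        records += [make_record(f"n{i}", False) for i in range(342)]
        summary = summarize_cohort(records)
        assert summary.n_total == 684
        assert summary.n_cases == summary.n_controls == 342

    def test_single_record_is_100_percent(self):
        summary = summarize_cohort([make_record("s0", True, drinking="no")])
        assert summary.level_counts["drinking"]["no"]["pct_cases"] == 100.0

    def test_counts_match_direct_tally(self, rng):
        levels = ("no", "occasionally", "regular")
        records = [
            make_record(f"s{i}", bool(i % 2), drinking=levels[rng.integers(3)])
            for i in range(200)
        ]
        summary = summarize_cohort(records)
        for level in levels:
            expected = sum(
                1 for r in records if r.is_case and r.exposures["drinking"] == level
            )
            assert summary.level_counts["drinking"][level]["cases"] == expected

    def test_percentages_sum_to_100(self, rng):
        levels = ("no", "occasionally", "regular")
        records = [
            make_record(f"s{i}", bool(i % 2), drinking=levels[rng.integers(3)])
            for i in range(100)
        ]
        tallies = summarize_cohort(records).level_counts["drinking"]
        assert sum(c["pct_cases"] for c in tallies.values()) == pytest.approx(100.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(DomainError):
            summarize_cohort([])
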