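"""Parsing, deduplication and report assembly."""

import pytest

from pvsignal import ingest
from pvsignal.errors import EmptyCohortError, FormatError


def write_quarter(tmp_path, demo_rows, drug_rows=(), reac_rows=(), ther_rows=()):
    files = {}
    headers = {
        "demo": "primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$occp_cod$reporter_country",
        "drug": "primaryid$drug_seq$role_cod$drugname",
        "reac": "primaryid$pt",
        "ther": "primaryid$dsg_drug_seq$start_dt",
    }
    for name, rows in (("demo", demo_rows), ("drug", drug_rows),
                       ("reac", reac_rows), ("ther", ther_rows)):
        p = tmp_path / f"{name}.txt"
        p.write_text("\n".join([headers[name], *("$".join(r) for r in rows)]) + "\n")
        files[name] = p
    return files


DEMO3 = [
    ["1", "100", "20230101", "20230102", "65", "YR", "M", "MD", "US"],
    ["2", "101", "20230201", "202302", "70", "YR", "F", "CN", "DE"],
    ["3", "102", "20230301", "", "", "", "", "", ""],
]


class TestReadQuarter:
    def test_parses_all_rows_and_keeps_dates_as_strings(self, tmp_path):
        files = write_quarter(tmp_path, DEMO3)
        rs = ingest.read_quarter(files)
        assert len(rs.demo) == 3
        assert rs.demo.loc[1, "event_dt"] == "202302"
        assert ingest.date_completeness("202302") == "partial"
        assert ingest.date_completeness("20230102") == "full"
        assert ingest.date_completeness("") == "missing"

    def test_missing_required_column_names_file_and_column(self, tmp_path):
        files = write_quarter(tmp_path, DEMO3)
        bad = tmp_path / "drug_bad.txt"
        bad.write_text("primaryid$drug_seq$drugname\n1$1$CARBOPLATIN\n")
        files["drug"] = bad
        with pytest.raises(FormatError, match="role_cod"):
            ingest.read_quarter(files)

    def test_empty_file_yields_empty_table(self, tmp_path):
        files = write_quarter(tmp_path, DEMO3)
        (tmp_path / "reac.txt").write_text("")
        rs = ingest.read_quarter(files)
        assert len(rs.reac) == 0


class TestDeduplicate:
    def _dedup_demo(self, tmp_path, rows):
        files = write_quarter(tmp_path, rows)
        return ingest.deduplicate(ingest.read_quarter(files)).demo

    def test_most_recent_receive_date_wins(self, tmp_path):
        # later fda_dt wins even though its primaryid is lower
        demo = self._dedup_demo(tmp_path, [
            ["1001", "100", "20230101", "", "", "", "", "", ""],
            ["1000", "100", "20230601", "", "", "", "", "", ""],
        ])
        assert list(demo["primaryid"]) == ["1000"]

    def test_tied_date_highest_primaryid_wins(self, tmp_path):
        demo = self._dedup_demo(tmp_path, [
            ["5", "7", "20230101", "", "", "", "", "", ""],
            ["9", "7", "20230101", "", "", "", "", "", ""],
        ])
        assert list(demo["primaryid"]) == ["9"]

    def test_unique_caseid_unchanged_and_idempotent(self, tmp_path):
        files = write_quarter(tmp_path, DEMO3,
                              reac_rows=[["1", "ANAEMIA"], ["2", "NAUSEA"]])
        rs = ingest.read_quarter(files)
        once = ingest.deduplicate(rs)
        twice = ingest.deduplicate(once)
        assert list(once.demo["primaryid"]) == ["1", "2", "3"]
        assert once.demo.equals(twice.demo)
        assert once.reac.equals(twice.reac)

    def test_child_rows_restricted_to_survivors(self, tmp_path):
        files = write_quarter(
            tmp_path,
            [["1", "100", "20230101", "", "", "", "", "", ""],
             ["2", "100", "20230601", "", "", "", "", "", ""]],
            drug_rows=[["1", "1", "PS", "OLD"], ["2", "1", "PS", "NEW"]],
            reac_rows=[["1", "ANAEMIA"], ["2", "NAUSEA"]])
        out = ingest.deduplicate(ingest.read_quarter(files))
        assert set(out.drug["primaryid"]) == {"2"}
        assert list(out.reac["pt"]) == ["NAUSEA"]


class TestNormalization:
    def test_synonym_resolution_after_cleanup(self):
        syn = {"PARAPLATIN": "CARBOPLATIN"}
        assert ingest.normalize_drug_name("  paraplatin ", syn) == "CARBOPLATIN"
        assert ingest.normalize_drug_name("Carbo-Platin!", {}) == "CARBO PLATIN"

    @pytest.mark.parametrize("age,cod,years", [
        ("780", "MON", 65.0),
        ("65", "YR", 65.0),
        ("7", "DEC", 70.0),
        ("730.5", "DY", 2.0),
    ])
    def test_age_unit_conversion(self, age, cod, years):
        got, fallback = ingest.age_to_years(age, cod)
        assert got == pytest.approx(years)
        assert not fallback

    def test_unknown_age_unit_treated_as_years_with_flag(self):
        got, fallback = ingest.age_to_years("66", "")
        assert got == 66.0 and fallback

    @pytest.mark.parametrize("years,label", [
        (17.9, "<18"), (18.0, "18-64.9"), (64.99, "18-64.9"),
        (65.0, "65-84.9"), (84.9, "65-84.9"), (85.0, ">85"), (100, ">85"),
    ])
    def test_age_bins_are_half_open(self, years, label):
        assert ingest.age_group_of(years) == label

    @pytest.mark.parametrize("code,cls", [
        ("MD", "healthcare-professional"), ("RN", "healthcare-professional"),
        ("CN", "non-healthcare-professional"), ("LW", "non-healthcare-professional"),
        ("", None), ("XX", None),
    ])
    def test_reporter_class(self, code, cls):
        assert ingest.reporter_class_of(code) == cls


class TestAssembleAndCohort:
    def _reports(self, tmp_path):
        files = write_quarter(
            tmp_path,
            [["1", "100", "20230101", "20230215", "780", "MON", "M", "CN", "US"],
             ["2", "101", "20180601", "", "55", "YR", "F", "MD", "DE"],
             ["3", "102", "20200301", "", "", "", "", "", "JP"]],
            drug_rows=[["1", "1", "PS", " paraplatin "],
                       ["2", "1", "C", "CARBOPLATIN"],
                       ["2", "2", "PS", "DRUGX"],
                       ["3", "1", "PS", "DRUGY"]],
            reac_rows=[["1", "ANAEMIA"], ["1", "ANAEMIA"], ["1", "NAUSEA"],
                       ["2", "RASH"], ["3", "NAUSEA"]],
            ther_rows=[["1", "1", "20230120"]])
        rs = ingest.deduplicate(ingest.read_quarter(files))
        return ingest.assemble_reports(rs, synonyms={"PARAPLATIN": "CARBOPLATIN"})

    def test_assembly_normalizes_and_collapses_duplicate_pts(self, tmp_path):
        reports, summary = self._reports(tmp_path)
        r1 = next(r for r in reports if r.primaryid == "1")
        assert r1.drugs[0].name_normalized == "CARBOPLATIN"
        assert r1.drugs[0].therapy_start == "20230120"
        assert r1.events == {"ANAEMIA", "NAUSEA"}  # repeated PT collapsed
        assert r1.age_years == pytest.approx(65.0)
        assert r1.age_group == "65-84.9"
        assert r1.reporter_class == "non-healthcare-professional"
        assert r1.report_year == 2023
        assert summary.n_reports == 3
        assert summary.n_event_pairs == 4  # pairs conserved, dup PT dropped

    def test_index_cohort_requires_primary_suspect_role(self, tmp_path):
        reports, _ = self._reports(tmp_path)
        index, background = ingest.select_index_cohort(reports, "CARBOPLATIN")
        assert {r.primaryid for r in index} == {"1"}  # role C does not qualify
        assert len(index) + len(background) == len(reports)

    def test_empty_index_cohort_is_an_error(self, tmp_path):
        reports, _ = self._reports(tmp_path)
        with pytest.raises(EmptyCohortError):
            ingest.select_index_cohort(reports, "NOSUCHDRUG")

    def test_unmapped_pt_counted_not_dropped(self, tmp_path):
        files = write_quarter(
            tmp_path,
            [["1", "100", "20230101", "", "", "", "", "", ""]],
            drug_rows=[["1", "1", "PS", "CARBOPLATIN"]],
            reac_rows=[["1", "WEIRDTERM"]])
        hier = ingest.EventHierarchy(pt_to_soc={"ANAEMIA": "BLOOD"})
        reports, summary = ingest.assemble_reports(
            ingest.read_quarter(files), hierarchy=hier)
        assert summary.n_unmapped_pts == 1
        assert reports[0].soc_events(hier) == {ingest.UNMAPPED_SOC}

    def test_roundtrip_jsonl(self, tmp_path):
        reports, _ = self._reports(tmp_path)
        path = tmp_path / "reports.jsonl"
        ingest.reports_to_jsonl(reports, path)
        back = ingest.reports_from_jsonl(path)
        assert [r.primaryid for r in back] == [r.primaryid for r in reports]
        assert back[0].events == reports[0].events
        assert back[0].drugs == reports[0].drugs
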