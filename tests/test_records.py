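"""Record model, CSV round trips, validation rules, site normalization."""

import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from psqakit import (
    GammaCriterion,
    filter_records,
    normalize_site,
    read_records,
    write_records,
)
from psqakit.vocab import SITES, UNMAPPED

from conftest import make_record

HEADER = (
    "patient_key,facility,machine,qa_device,site,qa_date,approval_date,"
    "gamma_3_3,gamma_2_2,dose_diff_pct"
)


def write_csv(tmp_path, rows, header=HEADER):
    path = tmp_path / "cohort.csv"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


VALID_ROW = "P00001,UniversityHospital,Clinac iX,ArcCHECK,Pelvis,2020-01-01,2019-12-29,99.1,95.0,0.3"


class TestGammaCriterion:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("3/3", (3.0, 3.0)),
            ("3%/3mm", (3.0, 3.0)),
            ("gamma_2_2", (2.0, 2.0)),
            ("2%/2 mm", (2.0, 2.0)),
        ],
    )
    def test_parse(self, text, expected):
        c = GammaCriterion.parse(text)
        assert (c.dose_pct, c.dta_mm) == expected

    def test_label_and_column(self):
        c = GammaCriterion(3, 3)
        assert c.label == "3%/3mm"
        assert c.column == "gamma_3_3"

    def test_nonpositive_tolerances_rejected(self):
        with pytest.raises(ValueError):
            GammaCriterion(0, 3)


class TestValidation:
    def test_all_valid_rows_accepted(self, tmp_path):
        rows = [VALID_ROW, VALID_ROW.replace("P00001", "P00002"),
                VALID_ROW.replace("P00001", "P00003")]
        records, report = read_records(write_csv(tmp_path, rows))
        assert len(records) == 3
        assert (report.accepted, report.rejected) == (3, 0)
        assert report.issues == []

    def test_gamma_above_scale_maximum_rejected(self, tmp_path):
        bad = VALID_ROW.replace("99.1", "104.2")
        records, report = read_records(write_csv(tmp_path, [VALID_ROW, bad]))
        assert len(records) == 1
        assert report.rejected == 1
        (issue,) = [i for i in report.errors if i.field == "gamma_3_3"]
        assert issue.rule == "out_of_range"

    def test_empty_site_rejected(self, tmp_path):
        bad = VALID_ROW.replace("Pelvis", "")
        records, report = read_records(write_csv(tmp_path, [bad]))
        assert records == []
        assert report.rejected == 1
        assert any(i.field == "site" and i.severity == "error" for i in report.issues)

    def test_unmapped_site_rejected_unknown_machine_warned(self, tmp_path):
        unmapped = VALID_ROW.replace("Pelvis", "elbow")
        odd_machine = VALID_ROW.replace("Clinac iX", "MysteryLinac")
        records, report = read_records(write_csv(tmp_path, [unmapped, odd_machine]))
        assert len(records) == 1  # warning keeps the row
        assert report.rejected == 1
        assert any(i.rule == "unmapped_site" for i in report.errors)
        assert any(i.rule == "unknown_vocabulary" for i in report.warnings)

    def test_dose_diff_outside_plausibility_window_rejected(self, tmp_path):
        bad = VALID_ROW.replace(",0.3", ",42.0")
        records, report = read_records(write_csv(tmp_path, [bad]))
        assert records == []
        assert any(i.field == "dose_diff_pct" for i in report.errors)

    def test_partition_identity(self, tmp_path):
        rows = [VALID_ROW, VALID_ROW.replace("99.1", "104.2"),
                VALID_ROW.replace("Pelvis", ""), VALID_ROW.replace("P00001", "P00009")]
        _, report = read_records(write_csv(tmp_path, rows))
        assert report.accepted + report.rejected == len(rows)
        assert all(
            any(i.row == r and i.severity == "error" for i in report.issues)
            for r in (1, 2)
        )

    def test_missing_mandatory_column_is_hard_failure(self, tmp_path):
        header = HEADER.replace("site,", "")
        row = VALID_ROW.replace("Pelvis,", "")
        with pytest.raises(ValueError, match="site"):
            read_records(write_csv(tmp_path, [row], header=header))


class TestRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path, small_cohort):
        path = tmp_path / "out.csv"
        write_records(small_cohort, path)
        back, report = read_records(path)
        assert report.rejected == 0
        assert back == small_cohort

    def test_empty_list_gives_header_only_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_records([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert "patient_key" in lines[0]

    def test_missing_optionals_stay_missing(self, tmp_path):
        rec = make_record(dose_diff=None)
        rec.approval_date = None
        path = tmp_path / "opt.csv"
        write_records([rec], path)
        (back,), _ = read_records(path)
        assert back.dose_diff_pct is None
        assert back.approval_date is None


class TestNormalizeSite:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("head and neck", "HeadNeck"),
            ("CNS", "CNS"),
            ("prostate", "Pelvis"),
            ("  LUNG ", "Chest"),
            ("elbow", UNMAPPED),
            ("", UNMAPPED),
            (None, UNMAPPED),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_site(raw) == expected

    @given(st.text(max_size=30))
    def test_idempotent(self, raw):
        once = normalize_site(raw)
        assert normalize_site(once) == once
        assert once in (*SITES, UNMAPPED)


class TestFilter:
    def test_empty_query_is_identity(self, small_cohort):
        assert filter_records(small_cohort) == small_cohort

    def test_site_query_counts(self, small_cohort):
        subset = filter_records(small_cohort, site="Pelvis")
        assert len(subset) == 2
        assert [r.patient_key for r in subset] == ["P00000", "P00002"]

    def test_date_window_inclusive_and_exhaustible(self, small_cohort):
        subset = filter_records(
            small_cohort, date_from="2020-01-02", date_to="2020-01-03"
        )
        assert len(subset) == 2  # both endpoints included
        assert filter_records(small_cohort, date_from="2030-01-01") == []

    def test_unknown_vocabulary_value_fails(self, small_cohort):
        with pytest.raises(ValueError):
            filter_records(small_cohort, site="Elbow")
        with pytest.raises(ValueError):
            filter_records(small_cohort, facility="Nowhere")

    def test_criterion_filter(self, small_cohort):
        assert filter_records(small_cohort, criterion="2/2") == []
        assert len(filter_records(small_cohort, criterion="3/3")) == 5
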