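"""Record validation, CSV round-trips and completeness auditing."""

import textwrap

import pytest

import mrmcroc as m
from mrmcroc.io import read_ratings, read_truth, validate_completeness

from conftest import make_rating


def write(tmp_path, name, body):
    p = tmp_path / name
    p.write_text(textwrap.dedent(body))
    return p


TRUTH_HEADER = ("case_id,patient_id,side,truth,density,finding_type,"
                "lesion_size_mm,histology\n")
RATING_HEADER = "case_id,reader_id,mode,session,bi_rads,pom\n"


class TestTruthParsing:
    def test_well_formed_rows_parse_identically(self, tmp_path):
        p = write(tmp_path, "t.csv", TRUTH_HEADER + (
            "c1,p1,left,malignant,dense,mass,19,idc\n"
            "c2,p1,right,normal_negative,dense,none,,\n"
            "c3,p2,left,benign_biopsy,non_dense,calcification,12,\n"
            "c4,p2,right,malignant,non_dense,mass_calc,30,dcis\n"))
        truths = read_truth(p)
        assert len(truths) == 4
        assert truths[0].lesion_size_mm == 19.0
        assert truths[1].lesion_size_mm is None and truths[1].histology is None
        assert truths[2].truth == "benign_biopsy"

    def test_case_insensitive_values_normalized(self, tmp_path):
        p = write(tmp_path, "t.csv", TRUTH_HEADER +
                  "c1,p1,Left,Malignant,DENSE,Mass,19,\n")
        assert read_truth(p)[0].truth == "malignant"
        assert read_truth(p)[0].density == "dense"

    def test_unknown_category_is_schema_error_naming_row(self, tmp_path):
        p = write(tmp_path, "t.csv", TRUTH_HEADER +
                  "c1,p1,left,malignant,unknown,mass,19,\n")
        with pytest.raises(m.SchemaError, match="line 2.*density"):
            read_truth(p)

    def test_duplicate_case_id_rejected(self, tmp_path):
        p = write(tmp_path, "t.csv", TRUTH_HEADER +
                  "c1,p1,left,malignant,dense,mass,19,\n"
                  "c1,p1,right,normal_negative,dense,none,,\n")
        with pytest.raises(m.IntegrityError, match="duplicate"):
            read_truth(p)

    def test_normal_breast_with_finding_rejected(self):
        with pytest.raises(m.IntegrityError):
            m.CaseTruth(case_id="c", patient_id="p", side="left",
                        truth="normal_negative", density="dense",
                        finding_type="mass")

    def test_lesion_size_without_finding_rejected(self):
        with pytest.raises(m.IntegrityError):
            m.CaseTruth(case_id="c", patient_id="p", side="left",
                        truth="normal_negative", density="dense",
                        lesion_size_mm=10.0)


class TestRatingParsing:
    def test_pom_value_kept_and_absent_distinct_from_zero(self, tmp_path):
        p = write(tmp_path, "r.csv", RATING_HEADER +
                  "c1,r1,DM,1,4,65\nc1,r2,DM,1,2,\nc1,r3,DM,1,3,0\n")
        recs = read_ratings(p)
        assert recs[0].pom == 65
        assert recs[1].pom is None
        assert recs[2].pom == 0

    def test_bi_rads_out_of_range_rejected(self, tmp_path):
        p = write(tmp_path, "r.csv", RATING_HEADER + "c1,r1,DM,1,6,90\n")
        with pytest.raises(m.SchemaError, match="line 2"):
            read_ratings(p)

    def test_missing_pom_for_suspicious_score_is_integrity_error(self, tmp_path):
        p = write(tmp_path, "r.csv", RATING_HEADER + "c1,r1,DM,1,4,\n")
        with pytest.raises(m.IntegrityError, match="requires a POM"):
            read_ratings(p)

    def test_pom_on_negative_score_warns_and_drops_or_raises(self, tmp_path):
        p = write(tmp_path, "r.csv", RATING_HEADER + "c1,r1,DM,1,2,40\n")
        with pytest.warns(UserWarning, match="protocol"):
            recs = read_ratings(p, on_protocol_violation="warn")
        assert recs[0].pom is None
        with pytest.raises(m.IntegrityError):
            read_ratings(p, on_protocol_violation="raise")

    def test_mode_session_mismatch_rejected(self, tmp_path):
        p = write(tmp_path, "r.csv", RATING_HEADER + "c1,r1,DM,2,1,\n")
        with pytest.raises(m.IntegrityError, match="session"):
            read_ratings(p)


class TestRoundTrip:
    def test_dataset_round_trips_field_for_field(self, small_study, tmp_path):
        m.write_dataset(small_study, tmp_path)
        back = m.read_dataset(tmp_path / "truth.csv", tmp_path / "ratings.csv")
        assert back.truths == small_study.truths
        assert back.ratings == small_study.ratings


class TestCompleteness:
    def test_full_study_has_no_findings_and_session_reports_counted(
            self, small_study, small_cfg):
        rep = validate_completeness(small_study)
        assert rep.is_complete
        n = small_cfg.n_breasts
        assert rep.n_ratings == n * small_cfg.n_readers * 2
        assert rep.expected_ratings == rep.n_ratings
        assert rep.session_report_count == n * small_cfg.n_readers * 2

    def test_one_deleted_rating_listed_as_missing(self, small_study):
        ds = m.StudyDataset(truths=small_study.truths,
                            ratings=small_study.ratings[1:],
                            metadata={})
        rep = validate_completeness(ds)
        gone = small_study.ratings[0]
        assert rep.missing == [(gone.case_id, gone.reader_id, gone.mode)]
        assert not rep.is_complete

    def test_orphan_rating_listed(self, tiny_dataset):
        tiny_dataset.ratings.append(make_rating("GHOST", "R1", "DM", 1))
        rep = validate_completeness(tiny_dataset)
        assert ("GHOST", "R1", "DM") in rep.orphans

    def test_duplicate_triple_listed(self, tiny_dataset):
        tiny_dataset.ratings.append(tiny_dataset.ratings[0])
        rep = validate_completeness(tiny_dataset)
        r = tiny_dataset.ratings[0]
        assert (r.case_id, r.reader_id, r.mode) in rep.duplicates

    def test_report_serializes_to_json(self, tiny_dataset, tmp_path):
        import json
        rep = validate_completeness(tiny_dataset)
        text = rep.to_json(tmp_path / "v.json")
        assert json.loads(text)["is_complete"] is True
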