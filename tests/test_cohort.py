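"""Trait grouping, treatment dating, time restriction and matching."""

import numpy as np
import pandas as pd
import pytest

from traitphewas.cohort import (
    Cohort,
    CohortError,
    TraitCuts,
    assign_trait_group,
    detect_treatment_start,
    match_controls,
    prepare_study_population,
    restrict_post_treatment,
    select_index_assay,
)


class TestTraitGroup:
    @pytest.mark.parametrize(
        "activity, expected",
        [(8.4, "low"), (15.0, "very_high"), (8.5, "normal"), (0.0, "low"),
         (14.99, "normal"), (25.0, "very_high")],
    )
    def test_cutpoint_boundaries(self, activity, expected):
        assert assign_trait_group(activity) == expected

    def test_negative_activity_rejected(self):
        with pytest.raises(CohortError):
            assign_trait_group(-1.0)

    def test_cuts_must_be_ordered(self):
        with pytest.raises(CohortError):
            TraitCuts(15.0, 8.5)


class TestIndexAssay:
    def test_earliest_assay_wins(self):
        assays = pd.DataFrame(
            {"date": pd.to_datetime(["2005-06-01", "2003-01-01"]),
             "activity": [12.8, 12.0]}
        )
        date, activity, stable = select_index_assay(assays)
        assert date == pd.Timestamp("2003-01-01")
        assert activity == 12.0
        assert stable

    def test_group_crossing_flags_unstable_but_keeps_first(self):
        assays = pd.DataFrame(
            {"date": pd.to_datetime(["2003-01-01", "2004-01-01"]),
             "activity": [14.9, 15.2]}
        )
        date, activity, stable = select_index_assay(assays)
        assert activity == 14.9
        assert not stable
        assert assign_trait_group(activity) == "normal"

    def test_no_assays_is_an_error(self):
        with pytest.raises(CohortError):
            select_index_assay(pd.DataFrame(columns=["date", "activity"]))


class TestTreatmentStart:
    def _mentions(self, rows):
        return pd.DataFrame(rows, columns=["date", "source", "payload"])

    def test_earliest_qualifying_mention_wins(self):
        m = self._mentions(
            [
                (pd.Timestamp("2005-03-01"), "report", "mise sous Imurel"),
                (pd.Timestamp("2005-06-01"), "cpoe", "AZATHIOPRINE"),
            ]
        )
        assert detect_treatment_start(m) == pd.Timestamp("2005-03-01")

    def test_non_matching_report_gives_none(self):
        m = self._mentions([(pd.Timestamp("2005-03-01"), "report", "paracetamol")])
        assert detect_treatment_start(m) is None

    def test_cpoe_counts_without_keyword_match(self):
        m = self._mentions([(pd.Timestamp("2010-02-02"), "cpoe",
                             "AZATHIOPRINE 50mg")])
        assert detect_treatment_start(m) == pd.Timestamp("2010-02-02")

    def test_accents_and_case_are_folded(self):
        m = self._mentions(
            [(pd.Timestamp("2007-01-01"), "report", "Poursuite de l'Imurel.")]
        )
        assert detect_treatment_start(m) == pd.Timestamp("2007-01-01")

    def test_empty_keyword_list_rejected(self):
        with pytest.raises(CohortError):
            detect_treatment_start(self._mentions([]), keywords=())


class TestPostTreatmentRestriction:
    def _streams(self):
        dx = pd.DataFrame(
            {
                "patient_id": ["p"] * 3,
                "date": pd.to_datetime(["2004-12-31", "2005-01-01", "2005-01-02"]),
                "code": ["K50", "K51", "K52"],
            }
        )
        labs = pd.DataFrame(columns=["patient_id", "date", "value"])
        return dx, labs

    def test_same_day_events_kept(self):
        dx, labs = self._streams()
        out_dx, _ = restrict_post_treatment(dx, labs, pd.Timestamp("2005-01-01"))
        assert list(out_dx["code"]) == ["K51", "K52"]

    def test_idempotent_and_monotone(self):
        dx, labs = self._streams()
        once_dx, _ = restrict_post_treatment(dx, labs, pd.Timestamp("2005-01-01"))
        twice_dx, _ = restrict_post_treatment(once_dx, labs,
                                              pd.Timestamp("2005-01-01"))
        assert len(once_dx) <= len(dx)
        assert twice_dx.reset_index(drop=True).equals(
            once_dx.reset_index(drop=True)
        )

    def test_empty_streams_pass_through(self):
        dx = pd.DataFrame(columns=["patient_id", "date", "code"])
        labs = pd.DataFrame(columns=["patient_id", "date", "value"])
        out_dx, out_labs = restrict_post_treatment(dx, labs,
                                                   pd.Timestamp("2005-01-01"))
        assert len(out_dx) == 0 and len(out_labs) == 0


class TestMatching:
    def _pool(self, n, sex="female", year=1970):
        return pd.DataFrame(
            {
                "patient_id": [f"c{i}" for i in range(n)],
                "sex": sex,
                "birth_year": year,
            }
        )

    def test_matches_on_sex_and_birth_year(self):
        index = pd.DataFrame(
            {"patient_id": ["i1"], "sex": ["female"], "birth_year": [1970]}
        )
        controls, shortfall = match_controls(index, self._pool(5), ratio=3, seed=7)
        assert len(controls) == 3
        assert (controls["sex"] == "female").all()
        assert (controls["birth_year"] == 1970).all()
        assert len(shortfall) == 0
        again, _ = match_controls(index, self._pool(5), ratio=3, seed=7)
        assert list(again["patient_id"]) == list(controls["patient_id"])

    def test_missing_stratum_warns_not_fails(self):
        index = pd.DataFrame(
            {"patient_id": ["i1"], "sex": ["male"], "birth_year": [1950]}
        )
        controls, shortfall = match_controls(index, self._pool(5), ratio=3, seed=1)
        assert len(controls) == 0
        assert shortfall.iloc[0]["missing"] == 3

    def test_no_control_selected_twice(self):
        index = pd.DataFrame(
            {
                "patient_id": ["i1", "i2", "i3"],
                "sex": "female",
                "birth_year": 1970,
            }
        )
        controls, shortfall = match_controls(index, self._pool(7), ratio=3, seed=3)
        assert controls["patient_id"].is_unique
        assert len(controls) + int(shortfall["missing"].sum()) == 9

    def test_overlapping_pool_rejected(self):
        index = pd.DataFrame(
            {"patient_id": ["c0"], "sex": ["female"], "birth_year": [1970]}
        )
        with pytest.raises(CohortError):
            match_controls(index, self._pool(3), ratio=3, seed=0)


class TestStudyPopulation:
    def test_flow_and_grouping(self, tiny_cohort_frames):
        cohort = Cohort(**tiny_cohort_frames)
        study = prepare_study_population(cohort)
        flow = dict(zip(study.flow["step"], study.flow["n"]))
        # p4's only mention has no drug keyword -> dropped
        assert flow["cohort_patients"] == 4
        assert flow["study_population"] == 3
        groups = dict(zip(study.patients["patient_id"],
                          study.patients["trait_group"]))
        assert groups == {"p1": "very_high", "p2": "normal", "p3": "low"}
        assert study.unstable == ["p4"]
        # partition: each remaining patient is in exactly one group
        assert set(groups.values()) <= {"low", "normal", "very_high"}

    def test_pre_treatment_records_removed(self, tiny_cohort_frames):
        frames = tiny_cohort_frames
        # p1 treated from 2004-01-01; add an earlier diagnosis
        extra = pd.DataFrame(
            {
                "patient_id": ["p1"],
                "encounter_id": [""],
                "date": [pd.Timestamp("2003-06-01")],
                "code": ["E10"],
            }
        )
        frames["diagnoses"] = pd.concat([frames["diagnoses"], extra],
                                        ignore_index=True)
        study = prepare_study_population(Cohort(**frames))
        p1_codes = set(
            study.diagnoses[study.diagnoses["patient_id"] == "p1"]["code"]
        )
        assert "E10" not in p1_codes

    def test_roundtrip_through_files(self, tiny_cohort_frames, tmp_path):
        cohort = Cohort(**tiny_cohort_frames)
        cohort.write_dir(tmp_path / "bundle")
        back = Cohort.read_dir(tmp_path / "bundle")
        study_a = prepare_study_population(cohort)
        study_b = prepare_study_population(back)
        assert study_a.patients["trait_group"].tolist() == \
            study_b.patients["trait_group"].tolist()
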