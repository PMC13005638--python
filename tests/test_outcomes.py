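import numpy as np
import pandas as pd
import pytest

from adhera import (
    OutcomesConfig,
    build_outcome_table,
    detect_exacerbations,
    steroid_exposure,
    stratify,
    summarize_costs,
    summarize_hcru,
)

from conftest import (
    build_bundle,
    make_diagnosis,
    make_dispensing,
    make_encounter,
    make_patient,
)

INDEX = pd.Timestamp("2020-01-01")


def cohort_frame(pid="P1", biologic="mepolizumab"):
    return pd.DataFrame(
        {"patient_id": [pid], "index_date": [INDEX], "index_biologic": [biologic]}
    )


def bundle_with(dispensings=(), diagnoses=(), encounters=()):
    return build_bundle(
        patients=[make_patient("P1")],
        dispensings=list(dispensings) or [make_dispensing("P1", date=INDEX)],
        diagnoses=list(diagnoses),
        encounters=list(encounters),
    )


class TestOcsIvRule:
    def test_short_course_is_not_an_event(self):
        bundle = bundle_with(
            dispensings=[
                make_dispensing("P1", "ocs", "2020-02-10", days_supplied=2,
                                quantity=60.0, steroid_compound="prednisolone",
                                is_biologic=False)
            ],
            diagnoses=[make_diagnosis("P1", "asthma", "2020-02-10")],
        )
        events = detect_exacerbations(bundle, "P1", INDEX)
        assert len(events) == 0

    def test_course_in_month_before_diagnosis_counts(self):
        bundle = bundle_with(
            dispensings=[
                make_dispensing("P1", "ocs", "2020-03-25", days_supplied=10,
                                quantity=300.0, steroid_compound="prednisolone",
                                is_biologic=False)
            ],
            diagnoses=[make_diagnosis("P1", "asthma", "2020-04-02")],
        )
        events = detect_exacerbations(bundle, "P1", INDEX)
        assert events["event_type"].tolist() == ["ocs_iv_course"]

    def test_course_in_month_after_diagnosis_does_not_count(self):
        bundle = bundle_with(
            dispensings=[
                make_dispensing("P1", "ocs", "2020-03-10", days_supplied=10,
                                quantity=300.0, steroid_compound="prednisolone",
                                is_biologic=False)
            ],
            diagnoses=[make_diagnosis("P1", "asthma", "2020-02-20")],
        )
        assert len(detect_exacerbations(bundle, "P1", INDEX)) == 0

    def test_iv_steroid_in_diagnosis_month_counts(self):
        bundle = bundle_with(
            dispensings=[
                make_dispensing("P1", "iv_steroid", "2020-05-03", days_supplied=1,
                                quantity=125.0, steroid_compound="methylprednisolone",
                                is_biologic=False)
            ],
            diagnoses=[make_diagnosis("P1", "asthma", "2020-05-20")],
        )
        events = detect_exacerbations(bundle, "P1", INDEX)
        assert events["event_type"].tolist() == ["ocs_iv_course"]


class TestEventMerging:
    def test_ed_visits_three_days_apart_merge(self):
        bundle = bundle_with(
            encounters=[
                make_encounter("P1", "ed_visit", "2020-02-01"),
                make_encounter("P1", "ed_visit", "2020-02-04"),
            ]
        )
        events = detect_exacerbations(bundle, "P1", INDEX)
        assert events["event_type"].tolist() == ["ed_visit"]

    def test_ed_visits_seven_days_apart_stay_separate(self):
        bundle = bundle_with(
            encounters=[
                make_encounter("P1", "ed_visit", "2020-02-01"),
                make_encounter("P1", "ed_visit", "2020-02-08"),
            ]
        )
        events = detect_exacerbations(bundle, "P1", INDEX)
        assert events["event_type"].tolist() == ["ed_visit", "ed_visit"]

    def test_ed_on_admission_day_deduplicated_behind_flag(self):
        encounters = [
            make_encounter("P1", "ed_visit", "2020-02-01"),
            make_encounter("P1", "inpatient_admission", "2020-02-01", "2020-02-05"),
        ]
        bundle = bundle_with(encounters=encounters)
        both = detect_exacerbations(bundle, "P1", INDEX)
        assert sorted(both["event_type"]) == ["ed_visit", "hospital_admission"]
        deduped = detect_exacerbations(
            bundle, "P1", INDEX, OutcomesConfig(dedupe_ed_into_admission=True)
        )
        assert deduped["event_type"].tolist() == ["hospital_admission"]


class TestHcru:
    def test_no_encounters_all_zero(self):
        table = summarize_hcru(bundle_with(), cohort_frame())
        row = table.iloc[0]
        assert row[["allcause_admissions", "allcause_hospital_days",
                    "allcause_ed_visits", "asthma_admissions",
                    "asthma_hospital_days", "asthma_ed_visits"]].sum() == 0

    def test_inclusive_day_arithmetic(self):
        bundle = bundle_with(
            encounters=[
                make_encounter("P1", "inpatient_admission",
                               INDEX + pd.Timedelta(days=10),
                               INDEX + pd.Timedelta(days=14), asthma=False)
            ]
        )
        row = summarize_hcru(bundle, cohort_frame()).iloc[0]
        assert row["allcause_admissions"] == 1
        assert row["allcause_hospital_days"] == 5
        assert row["asthma_admissions"] == 0

    def test_stay_truncated_at_followup_boundary(self):
        bundle = bundle_with(
            encounters=[
                make_encounter("P1", "inpatient_admission",
                               INDEX + pd.Timedelta(days=360),
                               INDEX + pd.Timedelta(days=370))
            ]
        )
        row = summarize_hcru(bundle, cohort_frame()).iloc[0]
        assert row["allcause_hospital_days"] == 6  # days 360..365

    def test_asthma_counts_are_a_subset(self):
        bundle = bundle_with(
            encounters=[
                make_encounter("P1", "ed_visit", "2020-02-01", asthma=True),
                make_encounter("P1", "ed_visit", "2020-03-01", asthma=False),
            ]
        )
        row = summarize_hcru(bundle, cohort_frame()).iloc[0]
        assert row["allcause_ed_visits"] == 2 and row["asthma_ed_visits"] == 1


class TestCosts:
    def test_only_biologics_with_flag_false_is_zero(self):
        bundle = bundle_with(
            dispensings=[
                make_dispensing("P1", "mepolizumab", "2020-02-01", cost=170000.0)
            ]
        )
        out = summarize_costs(bundle, cohort_frame(), include_biologics=False)
        assert out["cost_allcause_excl_biologics"].iloc[0] == 0.0

    def test_simple_sum(self):
        bundle = bundle_with(
            dispensings=[
                make_dispensing("P1", "ics_laba", "2020-02-01", cost=1000.0,
                                is_biologic=False),
                make_dispensing("P1", "other", "2020-03-01", cost=2500.0,
                                is_biologic=False),
            ]
        )
        out = summarize_costs(bundle, cohort_frame())
        assert out["cost_allcause_incl_biologics"].iloc[0] == 3500.0

    def test_line_in_asthma_admission_is_asthma_related(self):
        bundle = bundle_with(
            dispensings=[
                make_dispensing("P1", "other", "2020-02-03", cost=999.0,
                                is_biologic=False)
            ],
            encounters=[
                make_encounter("P1", "inpatient_admission", "2020-02-01",
                               "2020-02-05", asthma=True)
            ],
        )
        out = summarize_costs(bundle, cohort_frame())
        assert out["cost_asthma_excl_biologics"].iloc[0] == 999.0

    def test_decomposition_and_ordering_on_synthetic_cohort(self, small_cohort):
        bundle = small_cohort["bundle"]
        cohort = small_cohort["result"].mpr_set
        out = summarize_costs(bundle, cohort)
        assert np.allclose(
            out["cost_allcause_incl_biologics"],
            out["cost_allcause_excl_biologics"] + out["cost_biologics"],
        )
        assert (out["cost_asthma_incl_biologics"]
                <= out["cost_allcause_incl_biologics"] + 1e-9).all()
        assert (out["cost_asthma_excl_biologics"]
                <= out["cost_allcause_excl_biologics"] + 1e-9).all()


class TestSteroidExposure:
    def test_no_rows(self):
        disp = bundle_with().dispensings.iloc[0:0]
        assert steroid_exposure(disp, INDEX) == (0.0, 0.0, False)

    def test_prednisolone_course(self):
        disp = build_bundle(
            dispensings=[
                make_dispensing("P1", "ocs", "2020-02-01", days_supplied=5,
                                quantity=200.0, steroid_compound="prednisolone",
                                is_biologic=False)
            ]
        ).dispensings
        cum, daily, used = steroid_exposure(disp, INDEX)
        assert (cum, daily, used) == (200.0, 40.0, True)

    @pytest.mark.parametrize(
        "compound, quantity, expected_mg",
        [
            ("methylprednisolone", 4.0, 5.0),
            ("hydrocortisone", 20.0, 5.0),
            ("dexamethasone", 0.75, 5.0025),
        ],
    )
    def test_prednisone_equivalents(self, compound, quantity, expected_mg):
        disp = build_bundle(
            dispensings=[
                make_dispensing("P1", "iv_steroid", "2020-02-01", days_supplied=1,
                                quantity=quantity, steroid_compound=compound,
                                is_biologic=False)
            ]
        ).dispensings
        cum, daily, used = steroid_exposure(disp, INDEX)
        assert cum == pytest.approx(expected_mg)
        assert daily == pytest.approx(expected_mg)

    def test_unknown_compound_skipped_with_warning(self):
        disp = build_bundle(
            dispensings=[
                make_dispensing("P1", "ocs", "2020-02-01", days_supplied=3,
                                quantity=90.0, steroid_compound="none",
                                is_biologic=False)
            ]
        ).dispensings
        with pytest.warns(UserWarning, match="unknown compound"):
            cum, daily, used = steroid_exposure(disp, INDEX)
        assert (cum, used) == (0.0, False)

    def test_overlapping_courses_count_distinct_days(self):
        disp = build_bundle(
            dispensings=[
                make_dispensing("P1", "ocs", "2020-02-01", days_supplied=5,
                                quantity=100.0, steroid_compound="prednisolone",
                                is_biologic=False),
                make_dispensing("P1", "ocs", "2020-02-03", days_supplied=5,
                                quantity=100.0, steroid_compound="prednisolone",
                                is_biologic=False),
            ]
        ).dispensings
        cum, daily, used = steroid_exposure(disp, INDEX)
        assert cum == 200.0
        assert daily == pytest.approx(200.0 / 7)  # days 31..37 distinct


class TestStratify:
    def frame(self):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(6)],
                "exac_total": [0.14, 0.14, 0.28, 0.28, 0.0, 0.0],
            }
        )

    def test_reference_relative_difference_is_zero(self):
        table = self.frame().iloc[:2]
        out = stratify(table, pd.Series(["adherent", "adherent"]))
        assert out["rel_diff_pct"].tolist() == [0.0]

    def test_doubling_is_plus_100_percent(self):
        table = self.frame().iloc[:4]
        groups = pd.Series(["adherent", "adherent", "discontinuation",
                            "discontinuation"])
        out = stratify(table, groups).set_index("group")
        assert out.loc["discontinuation", "rel_diff_pct"] == pytest.approx(100.0)

    def test_zero_reference_mean_is_flagged_undefined(self):
        table = self.frame().iloc[2:]
        groups = pd.Series(["adherent", "adherent", "discontinuation",
                            "discontinuation"], index=table.index)
        table = table.copy()
        table.loc[table.index[:2], "exac_total"] = [0.0, 0.0]
        out = stratify(table, groups).set_index("group")
        assert np.isnan(out.loc["discontinuation", "rel_diff_pct"])

    def test_shares_sum_to_100(self, small_cohort):
        from adhera import summaries_to_frame

        table = build_outcome_table(
            small_cohort["bundle"], small_cohort["result"].mpr_set
        )
        cats = summaries_to_frame(small_cohort["summaries"])[
            ["patient_id", "category"]
        ]
        merged = table.merge(cats, on="patient_id")
        out = stratify(merged.drop(columns="category"), merged["category"])
        per_outcome = out.groupby("outcome")["share_pct"].sum()
        assert np.allclose(per_outcome, 100.0)
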