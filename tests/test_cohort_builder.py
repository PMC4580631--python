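"""Cohort-construction tests against a hand-enumerated fixture and
brute-force window oracles."""

import numpy as np
import pandas as pd
import pytest

from coxcut.cohort_builder import (EligibilityCriteria, apply_censoring,
                                   apply_inclusion, build_cohort,
                                   derive_covariates, derive_outcome,
                                   identify_initiators)
from coxcut.synth_claims import _COMED_CODE


class TestIdentifyInitiators:
    def test_empty_claims(self):
        empty = pd.DataFrame(columns=["subject_id", "day", "record_type",
                                      "code_class", "prescriber"])
        assert len(identify_initiators(empty)) == 0

    def test_fixture_initiators(self, ten_subject_fixture):
        claims, demo, expected = ten_subject_fixture
        got = identify_initiators(claims)
        got = {r.subject_id: (r.arm, r.index_day)
               for r in got.itertuples()}
        assert got == expected["initiators"]

    def test_minimal_qualifying_pattern(self):
        claims = pd.DataFrame({
            "subject_id": ["A", "A"], "day": [10, 40],
            "record_type": "drug", "code_class": "statin",
            "prescriber": "gp"})
        got = identify_initiators(claims)
        assert len(got) == 1
        assert tuple(got.iloc[0]) == ("A", "statin", 10)

    def test_single_reimbursement_not_initiator(self):
        claims = pd.DataFrame({
            "subject_id": ["A"], "day": [10], "record_type": ["drug"],
            "code_class": ["fibrate"], "prescriber": ["gp"]})
        assert len(identify_initiators(claims)) == 0


class TestInclusion:
    def test_fixture_inclusion_and_flowchart(self, ten_subject_fixture):
        claims, demo, expected = ten_subject_fixture
        cand = identify_initiators(claims)
        rows, attrition = apply_inclusion(cand, claims, demo)
        assert set(rows["subject_id"]) == expected["included"]
        # hand-enumerated attrition: 5 initiators; age rule removes S07;
        # prior-CV rule removes S05
        remaining = dict(zip(attrition["rule"], attrition["remaining"]))
        assert remaining["initiator candidates"] == 5
        assert remaining["age/sex threshold"] == 4
        assert remaining["no cardiovascular event in washout"] == 3
        # counts never increase along the ordered rules
        assert (np.diff(attrition["remaining"]) <= 0).all()

    def test_male_50_boundary_included(self, ten_subject_fixture):
        claims, demo, expected = ten_subject_fixture
        rows, _ = apply_inclusion(identify_initiators(claims), claims, demo)
        assert "S06" in set(rows["subject_id"])   # male aged exactly 50

    def test_female_59_excluded(self, ten_subject_fixture):
        claims, demo, expected = ten_subject_fixture
        rows, _ = apply_inclusion(identify_initiators(claims), claims, demo)
        assert "S07" not in set(rows["subject_id"])

    def test_missing_demographics_names_subject(self, ten_subject_fixture):
        claims, demo, _ = ten_subject_fixture
        cand = identify_initiators(claims)
        with pytest.raises(KeyError, match="S01"):
            apply_inclusion(cand, claims, demo[demo.subject_id != "S01"])

    def test_monotone_in_relaxed_criteria(self, small_claims):
        claims, demo, truth, cfg = small_claims
        base = EligibilityCriteria()
        rows0, _ = apply_inclusion(identify_initiators(claims, base), claims,
                                   demo, base)
        relaxations = [
            EligibilityCriteria(min_disease_reimbursements=2),
            EligibilityCriteria(min_age_male=45, min_age_female=55),
            EligibilityCriteria(max_reimbursement_gap_days=365),
        ]
        for crit in relaxations:
            rows, _ = apply_inclusion(identify_initiators(claims, crit),
                                      claims, demo, crit)
            assert set(rows0["subject_id"]) <= set(rows["subject_id"])


class TestCovariates:
    def test_three_records_flag_two_do_not(self, ten_subject_fixture):
        claims, demo, _ = ten_subject_fixture
        rows, _ = apply_inclusion(identify_initiators(claims), claims, demo)
        rows = derive_covariates(rows, claims, demo)
        by = rows.set_index("subject_id")
        assert by.loc["S01", "metformin"] == 1    # 3 records in prior year
        assert by.loc["S06", "sulfa"] == 0        # only 2 records

    def test_no_prior_year_claims_all_zero(self, ten_subject_fixture):
        claims, demo, _ = ten_subject_fixture
        # S10 indexes at day 0: its qualification claims fall in the prior
        # year but nothing else does
        rows, _ = apply_inclusion(identify_initiators(claims), claims, demo)
        rows = derive_covariates(rows, claims, demo)
        by = rows.set_index("subject_id")
        for name in ("insulin", "aspirin", "clopidogrel", "depression"):
            assert by.loc["S10", name] == 0

    def test_brute_force_window_oracle(self, small_claims):
        """Exact agreement with a per-subject sliding-window counter."""
        claims, demo, truth, cfg = small_claims
        rows, _ = apply_inclusion(identify_initiators(claims), claims, demo)
        rows = derive_covariates(rows, claims, demo)
        drugs = claims[claims["record_type"] == "drug"]
        for _, r in rows.head(60).iterrows():
            sub = drugs[drugs["subject_id"] == r["subject_id"]]
            for name, code in _COMED_CODE.items():
                n = ((sub["code_class"] == code)
                     & (sub["day"] < r["index_day"])
                     & (sub["day"] >= r["index_day"] - 365)).sum()
                assert r[name] == int(n >= 3), (r["subject_id"], name)


class TestOutcome:
    def test_first_occurrence_only(self, ten_subject_fixture):
        claims, demo, _ = ten_subject_fixture
        rows, _ = apply_inclusion(identify_initiators(claims), claims, demo)
        rows = derive_outcome(rows, claims, admin_end_day=913)
        by = rows.set_index("subject_id")
        # S06: stroke at day 110 (index 10), death at 210 -> stroke at 100
        assert by.loc["S06", "event"] == 1
        assert by.loc["S06", "event_type"] == "stroke"
        assert by.loc["S06", "followup_days"] == 100

    def test_no_event_censored_at_admin_end(self, ten_subject_fixture):
        claims, demo, _ = ten_subject_fixture
        rows, _ = apply_inclusion(identify_initiators(claims), claims, demo)
        rows = derive_outcome(rows, claims, admin_end_day=913)
        by = rows.set_index("subject_id")
        assert by.loc["S01", "event"] == 0
        assert by.loc["S01", "followup_days"] == 913 - 10

    def test_claim_order_invariance(self, ten_subject_fixture):
        claims, demo, _ = ten_subject_fixture
        rows, _ = apply_inclusion(identify_initiators(claims), claims, demo)
        a = derive_outcome(rows, claims, 913)
        shuffled = claims.sample(frac=1.0, random_state=3)
        b = derive_outcome(rows, shuffled, 913)
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))

    def test_amputation_excluded_endpoint(self, ten_subject_fixture):
        claims, demo, _ = ten_subject_fixture
        extra = pd.DataFrame({
            "subject_id": ["S01"], "day": [300],
            "record_type": ["hospital"], "code_class": ["cv_event_amputation"],
            "prescriber": ["na"]})
        claims2 = pd.concat([claims, extra], ignore_index=True)
        rows, _ = apply_inclusion(identify_initiators(claims2), claims2, demo)
        full = derive_outcome(rows, claims2, 913).set_index("subject_id")
        noamp = derive_outcome(rows, claims2, 913,
                               outcome_types=("death", "stroke", "mi")
                               ).set_index("subject_id")
        assert full.loc["S01", "event"] == 1
        assert full.loc["S01", "event_type"] == "amputation"
        assert noamp.loc["S01", "event"] == 0


class TestCensoring:
    @pytest.fixture()
    def outcome_rows(self, ten_subject_fixture):
        claims, demo, _ = ten_subject_fixture
        rows, _ = apply_inclusion(identify_initiators(claims), claims, demo)
        return derive_outcome(rows, claims, 913), claims

    def test_itt_identity(self, outcome_rows):
        rows, claims = outcome_rows
        pd.testing.assert_frame_equal(apply_censoring(rows, claims, "itt"),
                                      rows)

    def test_persistence_truncation(self, outcome_rows):
        """Reimbursements at 0 and 30 then none; event at 400 -> follow-up
        truncated at 30 + 183 = 213 with the event removed."""
        rows, claims = outcome_rows
        by = apply_censoring(rows, claims, "persistence").set_index("subject_id")
        assert by.loc["S10", "followup_days"] == 213
        assert by.loc["S10", "event"] == 0

    def test_switch_truncation(self, outcome_rows):
        """Fibrate initiator switching to statin at day 100 -> truncation at
        100 + 183 = 283."""
        rows, claims = outcome_rows
        by = apply_censoring(rows, claims, "switch").set_index("subject_id")
        assert by.loc["S10", "followup_days"] == 283
        assert by.loc["S10", "event"] == 0

    def test_unknown_rule_raises(self, outcome_rows):
        rows, claims = outcome_rows
        with pytest.raises(ValueError, match="unknown censoring rule"):
            apply_censoring(rows, claims, "per-protocol")

    def test_censoring_dominated_by_itt(self, small_claims):
        claims, demo, truth, cfg = small_claims
        itt, _ = build_cohort(claims, demo, rule="itt")
        for rule in ("persistence", "switch"):
            alt, _ = build_cohort(claims, demo, rule=rule)
            assert (alt["followup_days"].to_numpy()
                    <= itt["followup_days"].to_numpy()).all()
            assert alt["event"].sum() <= itt["event"].sum()
            assert (alt["event"].to_numpy()
                    <= itt["event"].to_numpy()).all()


class TestEndToEnd:
    def test_designed_exclusions_are_excluded(self, small_claims):
        """Cohort builder recovers the generator's designed verdicts."""
        claims, demo, truth, cfg = small_claims
        from coxcut.synth_claims import apply_designed_demographic_exclusions
        demo = apply_designed_demographic_exclusions(demo, truth)
        rows, _ = build_cohort(claims, demo)
        included = set(rows["subject_id"])
        designed = truth.set_index("subject_id")["design_group"]
        for sid in included:
            assert designed[sid] == "include", sid
        # every designed-includable subject is recovered
        want = set(designed[designed == "include"].index)
        assert included == want

    def test_outcomes_match_generator_truth(self, small_claims):
        claims, demo, truth, cfg = small_claims
        rows, _ = build_cohort(claims, demo)
        merged = rows.merge(truth[["subject_id", "followup_days", "event"]],
                            on="subject_id", suffixes=("", "_truth"))
        assert (merged["event"] == merged["event_truth"]).all()
        assert (merged["followup_days"] == merged["followup_days_truth"]).all()
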