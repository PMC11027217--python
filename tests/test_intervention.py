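import numpy as np
import pandas as pd
import pytest

from conftest import make_records
from ddiprev import coadmin as ca
from ddiprev import intervention as iv
from ddiprev.types import StudyWindow


def _pats(ids, genders=None):
    genders = genders or ["W"] * len(ids)
    return pd.DataFrame({"patient_id": ids, "gender": genders,
                         "birth_date": pd.Timestamp("1960-01-01")})


CLASSES = pd.DataFrame({"class_id": ["C1", "C1"], "drug_id": ["T", "A1"]})


class TestPlanSubstitutions:
    def test_clean_alternative_chosen(self, daily_window):
        recs = make_records([("p", "T", 0, 10), ("p", "X", 5, 10)],
                            daily_window)
        ddi = pd.DataFrame({"drug_a": ["T"], "drug_b": ["X"],
                            "severity": ["major"]})
        plan = iv.plan_substitutions(recs, "T", CLASSES, ddi, daily_window)
        assert len(plan) == 1
        assert plan.iloc[0]["action"] == "replaced"
        assert plan.iloc[0]["alternative"] == "A1"

    def test_all_alternatives_blocked(self, daily_window):
        recs = make_records([("p", "T", 0, 10), ("p", "X", 5, 10)],
                            daily_window)
        ddi = pd.DataFrame({"drug_a": ["T", "A1"], "drug_b": ["X", "X"],
                            "severity": ["major", "major"]})
        plan = iv.plan_substitutions(recs, "T", CLASSES, ddi, daily_window)
        assert plan.iloc[0]["action"] == "kept"
        assert plan.iloc[0]["blocked_by"] == "X"

    def test_episode_without_interaction_untouched(self, daily_window):
        recs = make_records([("p", "T", 0, 10), ("p", "Y", 5, 10)],
                            daily_window)
        ddi = pd.DataFrame({"drug_a": ["T"], "drug_b": ["X"],
                            "severity": ["major"]})
        plan = iv.plan_substitutions(recs, "T", CLASSES, ddi, daily_window)
        assert plan.empty

    def test_target_not_in_class_table_is_config_error(self, daily_window):
        recs = make_records([("p", "T", 0, 10)], daily_window)
        with pytest.raises(ValueError, match="class"):
            iv.plan_substitutions(recs, "Z", CLASSES,
                                  pd.DataFrame(columns=["drug_a", "drug_b",
                                                        "severity"]),
                                  daily_window)

    def test_alternative_order_prefers_fewest_interactions(self, daily_window):
        classes = pd.DataFrame({"class_id": ["C1"] * 3,
                                "drug_id": ["T", "A1", "A2"]})
        # A1 has one known interaction (not concurrent), A2 none:
        # A2 is tried first
        recs = make_records([("p", "T", 0, 10), ("p", "X", 5, 10)],
                            daily_window)
        ddi = pd.DataFrame({"drug_a": ["T", "A1"], "drug_b": ["X", "Y"],
                            "severity": ["major", "minor"]})
        plan = iv.plan_substitutions(recs, "T", classes, ddi, daily_window)
        assert plan.iloc[0]["alternative"] == "A2"

    def test_per_episode_decision(self, daily_window):
        # episode 1 has the interacting partner, episode 2 does not
        recs = make_records([("p", "T", 0, 10), ("p", "T", 50, 10),
                             ("p", "X", 5, 10)], daily_window)
        ddi = pd.DataFrame({"drug_a": ["T"], "drug_b": ["X"],
                            "severity": ["major"]})
        plan = iv.plan_substitutions(recs, "T", CLASSES, ddi, daily_window)
        assert len(plan) == 1
        assert (plan["start"] == daily_window.start_ts).all()


class TestApplyAndRecompute:
    def test_empty_plan_is_identity(self, daily_window):
        recs = make_records([("p", "T", 0, 10), ("p", "Y", 5, 10)],
                            daily_window)
        ddi = pd.DataFrame({"drug_a": ["T"], "drug_b": ["X"],
                            "severity": ["major"]})
        plan = iv.plan_substitutions(recs, "T", CLASSES, ddi, daily_window)
        report, new = iv.apply_and_recompute(recs, _pats(["p"]), ddi, plan,
                                             "T", daily_window)
        # strata with no patients carry null prevalences on both sides
        assert np.allclose(report["pi_before"], report["pi_after"],
                           equal_nan=True)

    def test_unit_accounting_single_patient(self, daily_window):
        # 5 patients; only p1 has a DDI (T+X); clean alternative exists:
        # overall PI drops by exactly 1/5
        rows = [("p1", "T", 0, 10), ("p1", "X", 5, 10)]
        rows += [(f"p{k}", "Y", 0, 10) for k in range(2, 6)]
        recs = make_records(rows, daily_window)
        pats = _pats([f"p{k}" for k in range(1, 6)])
        ddi = pd.DataFrame({"drug_a": ["T"], "drug_b": ["X"],
                            "severity": ["major"]})
        plan = iv.plan_substitutions(recs, "T", CLASSES, ddi, daily_window)
        report, _ = iv.apply_and_recompute(recs, pats, ddi, plan, "T",
                                           daily_window)
        row = report[(report.gender == "all") & (report.severity == "any")] \
            .iloc[0]
        assert row["pi_before"] - row["pi_after"] == pytest.approx(1 / 5)
        assert row["n_freed"] == 1

    def test_idempotent_application(self, daily_window):
        recs = make_records([("p", "T", 0, 10), ("p", "X", 5, 10)],
                            daily_window)
        ddi = pd.DataFrame({"drug_a": ["T"], "drug_b": ["X"],
                            "severity": ["major"]})
        plan = iv.plan_substitutions(recs, "T", CLASSES, ddi, daily_window)
        once = iv.apply_substitutions(recs, plan, "T", daily_window)
        twice = iv.apply_substitutions(once, plan, "T", daily_window)
        pd.testing.assert_frame_equal(once, twice)

    def test_conservation_of_administered_time(self, daily_window):
        recs = make_records([("p", "T", 0, 10), ("p", "T", 30, 7),
                             ("p", "X", 5, 10)], daily_window)
        ddi = pd.DataFrame({"drug_a": ["T"], "drug_b": ["X"],
                            "severity": ["major"]})
        plan = iv.plan_substitutions(recs, "T", CLASSES, ddi, daily_window)
        new = iv.apply_substitutions(recs, plan, "T", daily_window)
        before = recs.groupby("patient_id")["duration"].sum()
        after = new.groupby("patient_id")["duration"].sum()
        pd.testing.assert_series_equal(before, after)

    def test_substitution_never_creates_new_ddi(self, daily_window):
        # exhaustive re-scan after rewrite on a mixed cohort
        rows = [("p1", "T", 0, 20), ("p1", "X", 5, 10),
                ("p2", "T", 0, 20), ("p2", "X", 0, 5), ("p2", "Z", 10, 10),
                ("p3", "T", 0, 20), ("p3", "Y", 0, 20)]
        recs = make_records(rows, daily_window)
        pats = _pats(["p1", "p2", "p3"], ["W", "M", "W"])
        ddi = pd.DataFrame({
            "drug_a": ["T", "T", "A1"], "drug_b": ["X", "Y", "Z"],
            "severity": ["major", "moderate", "major"]})
        plan = iv.plan_substitutions(recs, "T", CLASSES, ddi, daily_window)
        new = iv.apply_substitutions(recs, plan, "T", daily_window)
        def ddi_set(r):
            eps = ca.detect_pair_episodes(r, ddi, daily_window)
            hit = eps[eps["is_ddi"]]
            return set(zip(hit["patient_id"], hit["drug_i"], hit["drug_j"]))
        before, after = ddi_set(recs), ddi_set(new)
        assert after <= before

    def test_pi_never_increases_in_any_stratum(self, daily_window):
        rows = [("p1", "T", 0, 20), ("p1", "X", 5, 10),
                ("p2", "T", 0, 20), ("p2", "X", 10, 10),
                ("p3", "Y", 0, 10), ("p4", "T", 0, 5)]
        recs = make_records(rows, daily_window)
        pats = _pats(["p1", "p2", "p3", "p4"], ["W", "M", "W", "M"])
        ddi = pd.DataFrame({"drug_a": ["T"], "drug_b": ["X"],
                            "severity": ["major"]})
        plan = iv.plan_substitutions(recs, "T", CLASSES, ddi, daily_window)
        report, _ = iv.apply_and_recompute(recs, pats, ddi, plan, "T",
                                           daily_window)
        assert (report["pi_after"] <= report["pi_before"] + 1e-12).all()
        assert report["relative_reduction"].between(0, 1).all()


def hub_fixture(daily_window):
    """Constructed hub-drug scenario: the hub H is involved in 75% of
    patients' interactions and a clean same-class alternative exists."""
    rows, genders, ids = [], [], []
    # 15 patients with H+X interactions (substitutable)
    for k in range(15):
        pid = f"h{k:02d}"
        rows += [(pid, "H", 0, 20), (pid, "X", 5, 10)]
        ids.append(pid)
        genders.append("W" if k % 2 else "M")
    # 5 patients with an unrelated interaction C+D (not substitutable)
    for k in range(5):
        pid = f"c{k:02d}"
        rows += [(pid, "C", 0, 20), (pid, "D", 5, 10)]
        ids.append(pid)
        genders.append("W" if k % 2 else "M")
    recs = make_records(rows, daily_window)
    pats = _pats(ids, genders)
    ddi = pd.DataFrame({"drug_a": ["H", "C"], "drug_b": ["X", "D"],
                        "severity": ["major", "major"]})
    classes = pd.DataFrame({"class_id": ["PPI", "PPI"],
                            "drug_id": ["H", "ALT"]})
    return recs, pats, ddi, classes


class TestHubScenario:
    def test_relative_reduction_at_least_half(self, daily_window):
        recs, pats, ddi, classes = hub_fixture(daily_window)
        plan = iv.plan_substitutions(recs, "H", classes, ddi, daily_window)
        report, _ = iv.apply_and_recompute(recs, pats, ddi, plan, "H",
                                           daily_window)
        row = report[(report.gender == "all")
                     & (report.severity == "any")].iloc[0]
        # 15 of 20 interacting patients are freed: reduction 0.75 >= 0.5
        assert row["relative_reduction"] >= 0.5
        assert row["n_freed"] == 15
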