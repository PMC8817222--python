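import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

from eirkit import eligibility as el
from eirkit.data_model import clean_bundle
from eirkit.schedule import default_schedule
from eirkit.synthetic_data import SimConfig, simulate_registry

BIRTH = dt.date(2018, 1, 1)


# ---------------------------------------------------------------------------
# independent brute-force oracle: evaluates each eligibility rule as a
# separate named predicate and requires all to hold
# ---------------------------------------------------------------------------

def oracle_eligible(schedule, history, birth, visit_date):
    age = (visit_date - birth).days
    result = set()
    for dose in schedule.doses:
        checks = [
            ("not already received", dose.key not in history),
            ("old enough", age >= dose.min_age_days),
            ("young enough", dose.max_age_days is None
             or age <= dose.max_age_days),
            ("sequence rule", _oracle_sequence_ok(schedule, dose, history,
                                                  age, visit_date)),
        ]
        if all(ok for _, ok in checks):
            result.add(dose.key)
    return result


def _oracle_sequence_ok(schedule, dose, history, age, visit_date):
    seq = schedule.sequence(dose.vaccine)
    pos = [d.dose_number for d in seq].index(dose.dose_number)
    if pos == 0:
        return True
    prev_key = (dose.vaccine, seq[pos - 1].dose_number)
    if prev_key in history:
        return (visit_date - history[prev_key]).days >= dose.min_interval_days
    if dose.vaccine == "OPV" and dose.dose_number == 1:
        # OPV-1 starts the sequence once the birth-dose window has closed
        return age > schedule.opv0_window_days
    return False


def random_case(schedule, rng):
    """Random (history, visit age) pair with dates consistent with ages."""
    age = int(rng.integers(0, 800))
    visit_date = BIRTH + dt.timedelta(days=age)
    history = {}
    for dose in schedule.doses:
        if rng.random() < 0.4 and age > 0:
            history[dose.key] = BIRTH + dt.timedelta(
                days=int(rng.integers(0, age)))
    return history, visit_date


class TestEligibleAt:
    def test_matches_oracle_on_randomized_cases(self, schedule):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            history, visit_date = random_case(schedule, rng)
            got = el.eligible_at(schedule, history, BIRTH, visit_date)
            want = oracle_eligible(schedule, history, BIRTH, visit_date)
            assert got == want, (history, visit_date)

    def test_six_weeks_empty_history(self, schedule):
        got = el.eligible_at(schedule, {}, BIRTH, BIRTH + dt.timedelta(42))
        # birth-dose window for OPV-0 has closed; BCG is still open
        assert got == {("BCG", 0), ("OPV", 1), ("Penta", 1), ("PCV", 1),
                       ("Rota", 1)}

    def test_interval_too_short_blocks_next_dose(self, schedule):
        history = {("Penta", 1): BIRTH + dt.timedelta(42 - 10)}
        got = el.eligible_at(schedule, history, BIRTH, BIRTH + dt.timedelta(42))
        assert ("Penta", 2) not in got

    def test_rota_never_eligible_after_first_year(self, schedule):
        got = el.eligible_at(schedule, {}, BIRTH, BIRTH + dt.timedelta(400))
        assert not any(v == "Rota" for v, _ in got)

    def test_opv1_without_opv0_after_window(self, schedule):
        got = el.eligible_at(schedule, {}, BIRTH, BIRTH + dt.timedelta(42))
        assert ("OPV", 1) in got and ("OPV", 0) not in got

    def test_mcv1_requires_nine_months(self, schedule):
        early = el.eligible_at(schedule, {}, BIRTH, BIRTH + dt.timedelta(273))
        ready = el.eligible_at(schedule, {}, BIRTH, BIRTH + dt.timedelta(274))
        assert ("MCV", 1) not in early and ("MCV", 1) in ready

    def test_visit_before_birth_is_an_error(self, schedule):
        with pytest.raises(ValueError):
            el.eligible_at(schedule, {}, BIRTH, BIRTH - dt.timedelta(1))


class TestAssessVisit:
    def _assess(self, schedule, given, missed=None, age=42, history=None):
        return el.assess_visit(
            schedule, visit_id="V", patient_id="P", facility_id="F",
            birth_date=BIRTH, visit_date=BIRTH + dt.timedelta(age),
            doses_given=given, missed_records=missed or {},
            history=history or {})

    def test_all_eligible_given_means_no_mov(self, schedule):
        eligible = el.eligible_at(schedule, {}, BIRTH, BIRTH + dt.timedelta(42))
        a = self._assess(schedule, eligible)
        assert a.mov_any is False and a.mov_count == 0

    def test_explicit_stockout_reason_attributed(self, schedule):
        eligible = sorted(el.eligible_at(schedule, {}, BIRTH,
                                         BIRTH + dt.timedelta(42)))
        withheld = eligible[-1]
        a = self._assess(schedule, set(eligible[:-1]),
                         missed={withheld: "stockout"})
        assert a.mov_count == 1
        assert a.reasons[withheld] == "stockout"

    def test_unrecorded_misses_get_reason_none(self, schedule):
        a = self._assess(schedule, set())
        assert a.mov_count == len(a.eligible_doses) > 0
        assert set(a.reasons.values()) == {"none"}

    def test_removing_given_dose_never_decreases_mov_count(self, schedule):
        eligible = sorted(el.eligible_at(schedule, {}, BIRTH,
                                         BIRTH + dt.timedelta(42)))
        counts = []
        for k in range(len(eligible), -1, -1):
            counts.append(self._assess(schedule, set(eligible[:k])).mov_count)
        assert counts == sorted(counts)

    def test_strict_who_mode_excludes_contraindicated(self, schedule):
        eligible = sorted(el.eligible_at(schedule, {}, BIRTH,
                                         BIRTH + dt.timedelta(42)))
        withheld = eligible[-1]
        a = el.assess_visit(
            schedule, visit_id="V", patient_id="P", facility_id="F",
            birth_date=BIRTH, visit_date=BIRTH + dt.timedelta(42),
            doses_given=set(eligible[:-1]),
            missed_records={withheld: "contraindication"}, strict_who=True)
        assert a.mov_count == 0


class TestBundleAssessment:
    def test_full_compliance_cohort_has_zero_movs(self, schedule):
        cfg = SimConfig(seed=3, n_children=150, mov_per_dose_prob=0.0,
                        back_entry_prob=0.0,
                        visit_continuation=(1, 1, 1, 1, 1, 1))
        bundle, _ = simulate_registry(cfg)
        live, _ = clean_bundle(bundle)
        assessments, missed = el.assess_bundle(live, schedule)
        assert int(assessments["mov_count"].sum()) == 0
        assert missed.empty

    def test_conservation_and_reason_tally(self, schedule, small_sim):
        bundle, _ = small_sim
        live, _ = clean_bundle(bundle)
        assessments, missed = el.assess_bundle(live, schedule)
        # total MOVs = per-vaccine sums = missed-record rows
        assert int(assessments["mov_count"].sum()) == len(missed)
        per_vac = missed.groupby("vaccine").size()
        for v, n in per_vac.items():
            assert int(assessments[f"mov_{v}"].sum()) <= n  # visit-level flag
        table = el.mov_reason_table(missed)
        overall = table[table["vaccine"] == "Overall"].iloc[0]
        assert overall["n_mov"] == len(missed)
        reason_total = sum(overall[f"n_{r}"] for r in
                           ["stockout", "contraindication", "late", "refusal",
                            "expired_stock", "none"])
        assert reason_total == len(missed)
        # grouped counts equal a per-record tally
        tally = missed.groupby(["vaccine", "reason"]).size()
        for (v, r), n in tally.items():
            row = table[table["vaccine"] == v].iloc[0]
            assert row[f"n_{r}"] == n

    def test_per_child_summary_matches_hand_computation(self, schedule):
        assessments = pd.DataFrame({
            "patient_id": ["a", "a", "b", "c"],
            "mov_count": [1, 2, 0, 3]})
        per_child, agg = el.per_child_mov_summary(assessments)
        assert dict(zip(per_child["patient_id"],
                        per_child["total_movs"])) == {"a": 3, "b": 0, "c": 3}
        assert agg["mean_movs"] == pytest.approx(2.0)
        assert agg["pct_ge1"] == pytest.approx(100 * 2 / 3)


class TestMovTables:
    def test_single_penta_mov_everywhere(self, schedule):
        assessments = pd.DataFrame({
            "visit_id": ["v1", "v2"], "patient_id": ["a", "b"],
            "mov_any": [True, True], "mov_count": [1, 1],
            "mov_Penta": [True, True], "mov_BCG": [False, False]})
        cov = pd.DataFrame({"visit_id": ["v1", "v2"], "sex": ["f", "m"]})
        t = el.mov_tables(assessments, cov, ["sex"])
        overall = t[t["variable"] == "overall"].iloc[0]
        assert overall["pct_mov_any"] == 100.0
        assert overall["pct_mov_Penta"] == 100.0
        assert overall["pct_mov_BCG"] == 0.0

    def test_unknown_stratum_is_an_error(self, schedule):
        assessments = pd.DataFrame({
            "visit_id": ["v1"], "patient_id": ["a"], "mov_any": [False],
            "mov_count": [0]})
        cov = pd.DataFrame({"visit_id": ["v1"]})
        with pytest.raises(KeyError):
            el.mov_tables(assessments, cov, ["nope"])

    def test_injected_per_visit_rate_recovered(self, schedule):
        cfg = SimConfig(seed=21, n_children=2500, mov_mode="per_visit",
                        mov_visit_prob=0.25, back_entry_prob=0.0,
                        movement_prob=0.0)
        bundle, truth = simulate_registry(cfg)
        live, _ = clean_bundle(bundle)
        assessments, _ = el.assess_bundle(live, schedule)
        n = len(assessments)
        p = truth.expected_mov_any_rate
        se = np.sqrt(p * (1 - p) / n)
        assert abs(assessments["mov_any"].mean() - p) < 3 * se
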