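import datetime as dt

import numpy as np
import pandas as pd
import pytest

from eirkit import data_model as dm


def test_write_read_round_trip(tmp_path, tiny_bundle):
    paths = dm.write_registry(tiny_bundle, tmp_path)
    back = dm.read_registry({n: paths[n] for n in dm.TABLE_NAMES})
    for name in dm.TABLE_NAMES:
        a = tiny_bundle.table(name).reset_index(drop=True)
        b = back.table(name).reset_index(drop=True)
        # empty visit links serialize as empty cells
        if name == "doses":
            a = a.assign(visit_id=a["visit_id"].replace("", np.nan))
        pd.testing.assert_frame_equal(a, b, check_dtype=False)


def test_missing_column_names_the_column(tmp_path, tiny_bundle):
    paths = dm.write_registry(tiny_bundle, tmp_path)
    df = pd.read_csv(paths["patients"]).drop(columns=["sex"])
    df.to_csv(paths["patients"], index=False)
    with pytest.raises(dm.SchemaError, match="sex"):
        dm.read_registry({n: paths[n] for n in dm.TABLE_NAMES})


def test_column_mapping_config(tmp_path, tiny_bundle):
    paths = dm.write_registry(tiny_bundle, tmp_path)
    df = pd.read_csv(paths["patients"]).rename(columns={"sex": "gender"})
    df.to_csv(paths["patients"], index=False)
    bundle = dm.read_registry(
        {n: paths[n] for n in dm.TABLE_NAMES},
        config={"column_map": {"patients": {"sex": "gender"}}})
    assert list(bundle.patients["sex"]) == list(tiny_bundle.patients["sex"])


def test_unresolvable_foreign_key_lists_ids(tiny_bundle):
    bad = tiny_bundle.copy()
    bad.patients.loc[0, "assigned_facility_id"] = "F99"
    with pytest.raises(dm.ValidationError, match="F99"):
        dm.validate_bundle(bad)


def test_malformed_date_row_goes_to_rejects(tmp_path, tiny_bundle):
    paths = dm.write_registry(tiny_bundle, tmp_path)
    df = pd.read_csv(paths["stock"], dtype=str)
    df.loc[1, "date"] = "not-a-date"
    df.to_csv(paths["stock"], index=False)
    bundle = dm.read_registry({n: paths[n] for n in dm.TABLE_NAMES})
    assert len(bundle.stock) == len(tiny_bundle.stock) - 1
    assert len(bundle.rejects) == 1
    assert bundle.rejects.iloc[0]["table"] == "stock"
    assert "date" in bundle.rejects.iloc[0]["reason"]


def _doses(rows):
    return pd.DataFrame(rows, columns=["patient_id", "visit_id", "vaccine",
                                       "dose_number", "date_given",
                                       "entry_mode", "missed_reason"])


def _dose(pid, vaccine, num, date, mode="live", reason="none"):
    return {"patient_id": pid, "visit_id": "", "vaccine": vaccine,
            "dose_number": num, "date_given": pd.Timestamp(date),
            "entry_mode": mode, "missed_reason": reason}


class TestCampaignExclusion:
    def test_four_repeats_excludes_patient_entirely(self):
        rows = [_dose("PX", "OPV", 1, f"2018-02-{d:02d}") for d in (1, 8, 15, 22)]
        rows.append(_dose("PX", "BCG", 0, "2018-01-01"))
        rows.append(_dose("PY", "OPV", 1, "2018-02-01"))
        kept, excluded = dm.exclude_campaign_ids(_doses(rows))
        assert excluded == {"PX"}
        assert set(kept["patient_id"]) == {"PY"}

    def test_three_repeats_retained(self):
        rows = [_dose("PX", "OPV", 1, f"2018-02-{d:02d}") for d in (1, 8, 15)]
        kept, excluded = dm.exclude_campaign_ids(_doses(rows))
        assert excluded == set()
        assert len(kept) == 3

    def test_empty_table(self):
        kept, excluded = dm.exclude_campaign_ids(_doses([]))
        assert kept.empty and excluded == set()

    def test_idempotent_and_matches_brute_force(self, small_sim):
        bundle, _ = small_sim
        doses = bundle.doses
        kept, excluded = dm.exclude_campaign_ids(doses)
        again, excluded2 = dm.exclude_campaign_ids(kept)
        assert excluded2 == set()
        pd.testing.assert_frame_equal(kept, again)
        # brute force: survivors are patients whose max slot count <= 3
        admin = doses[doses["missed_reason"] == "none"]
        survivors = {
            p for p, sub in admin.groupby("patient_id")
            if sub.groupby(["vaccine", "dose_number"]).size().max() <= 3}
        no_admin = set(doses["patient_id"]) - set(admin["patient_id"])
        assert set(kept["patient_id"]) <= survivors | no_admin
        assert excluded == set(doses["patient_id"]) - (survivors | no_admin)


class TestDedup:
    def test_keeps_earliest_date(self):
        rows = [_dose("PX", "PCV", 2, "2018-03-12"),
                _dose("PX", "PCV", 2, "2018-03-17")]
        out = dm.dedup_repeat_doses(_doses(rows))
        assert len(out) == 1
        assert out.iloc[0]["date_given"] == pd.Timestamp("2018-03-12")

    def test_single_record_unchanged(self):
        df = _doses([_dose("PX", "PCV", 2, "2018-03-12")])
        pd.testing.assert_frame_equal(dm.dedup_repeat_doses(df), df)

    def test_same_date_tie_keeps_first_input_row(self):
        rows = [_dose("PX", "PCV", 2, "2018-03-12"),
                _dose("PX", "PCV", 2, "2018-03-12"),
                _dose("PX", "PCV", 2, "2018-03-12")]
        df = _doses(rows)
        df["tag"] = ["a", "b", "c"]
        out = dm.dedup_repeat_doses(df)
        assert list(out["tag"]) == ["a"]

    def test_matches_brute_force_min_date(self, small_sim):
        bundle, _ = small_sim
        rng = np.random.default_rng(5)
        admin = bundle.administered
        extra = admin.sample(n=30, random_state=7).copy()
        extra["date_given"] = extra["date_given"] + pd.Timedelta(days=9)
        doses = pd.concat([bundle.doses, extra], ignore_index=True)
        out = dm.dedup_repeat_doses(doses)
        got = out[out["missed_reason"] == "none"].groupby(
            ["patient_id", "vaccine", "dose_number"])["date_given"].first()
        expected = doses[doses["missed_reason"] == "none"].groupby(
            ["patient_id", "vaccine", "dose_number"])["date_given"].min()
        pd.testing.assert_series_equal(got.sort_index(), expected.sort_index())


class TestRegionRestriction:
    @pytest.mark.parametrize("min_visits,dropped", [
        (0, set()),          # identity
        (4, {"RB"}),         # boundary: RA has exactly 4 visits by cutoff
        (5, {"RA", "RB"}),   # both regions below 5 (RB has none)
        (1, {"RB"}),
    ])
    def test_threshold_boundaries(self, tiny_bundle, min_visits, dropped):
        out, got = dm.restrict_regions(tiny_bundle, min_visits,
                                       dt.date(2019, 12, 31))
        assert got == dropped
        assert set(out.facilities["region"]) == {"RA", "RB"} - dropped

    def test_drop_cascades_to_all_tables(self, tiny_bundle):
        out, _ = dm.restrict_regions(tiny_bundle, 2, dt.date(2019, 12, 31))
        assert "F03" not in set(out.facilities["facility_id"])
        assert "P4" not in set(out.patients["patient_id"])
        assert "F03" not in set(out.stock["facility_id"])


class TestLiveFilter:
    def test_flag_false_keeps_only_live(self, tiny_bundle):
        out = dm.filter_live_doses(tiny_bundle.doses, False)
        assert (out["entry_mode"] == "live").all()

    def test_back_entered_only_patient_excluded(self, tiny_bundle):
        out = dm.filter_live_doses(tiny_bundle.doses, True)
        assert "P4" not in set(out["patient_id"])  # only back-entered doses

    def test_mixed_patient_keeps_all_rows(self, tiny_bundle):
        out = dm.filter_live_doses(tiny_bundle.doses, True)
        p3 = out[out["patient_id"] == "P3"]
        assert len(p3) == 2
        assert set(p3["entry_mode"]) == {"live", "back_entered"}

    def test_identity_on_all_live(self):
        df = _doses([_dose("PX", "BCG", 0, "2018-01-01")])
        pd.testing.assert_frame_equal(dm.filter_live_doses(df, False), df)


def test_commuting_cleaning_steps_give_same_result(small_sim):
    """Exclusion and region restriction commute on simulated registries."""
    bundle, _ = small_sim
    cutoff = dt.date(2019, 12, 31)

    _, excluded = dm.exclude_campaign_ids(bundle.doses)
    a = dm.apply_patient_exclusion(bundle, excluded)
    a, _ = dm.restrict_regions(a, 50, cutoff)

    b, _ = dm.restrict_regions(bundle, 50, cutoff)
    _, excluded_b = dm.exclude_campaign_ids(b.doses)
    b = dm.apply_patient_exclusion(b, excluded_b)

    for name in dm.TABLE_NAMES:
        pd.testing.assert_frame_equal(
            a.table(name).reset_index(drop=True),
            b.table(name).reset_index(drop=True))
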