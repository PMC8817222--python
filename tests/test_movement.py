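import numpy as np
import pandas as pd
import pytest

from eirkit import movement as mv
from eirkit.data_model import clean_bundle
from eirkit.synthetic_data import SimConfig, simulate_registry


class TestHaversine:
    def test_identical_points(self):
        assert mv.haversine_km(-6.0, 35.0, -6.0, 35.0) == 0.0

    def test_one_degree_longitude_at_equator(self):
        # 2*pi*R/360 = 111.19 km
        assert mv.haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.01)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(1)
        a = rng.uniform([-90, -180], [90, 180], size=(50, 2))
        b = rng.uniform([-90, -180], [90, 180], size=(50, 2))
        d1 = mv.haversine_km(a[:, 0], a[:, 1], b[:, 0], b[:, 1])
        d2 = mv.haversine_km(b[:, 0], b[:, 1], a[:, 0], a[:, 1])
        np.testing.assert_allclose(d1, d2)


def _geo_fixture():
    """Facilities with known pairwise distances (1 deg lat = 111.19 km)."""
    return pd.DataFrame([
        # A-B ~3.3km apart, same district; C same district but ~33km away;
        # D other district same region; E other region (adjacent!)
        {"facility_id": "A", "region": "R1", "district": "R1D1",
         "lat": 0.0, "lon": 30.0},
        {"facility_id": "B", "region": "R1", "district": "R1D1",
         "lat": 0.03, "lon": 30.0},
        {"facility_id": "C", "region": "R1", "district": "R1D1",
         "lat": 0.3, "lon": 30.0},
        {"facility_id": "D", "region": "R1", "district": "R1D2",
         "lat": 0.6, "lon": 30.0},
        {"facility_id": "E", "region": "R2", "district": "R2D1",
         "lat": 0.031, "lon": 30.0},
    ]).assign(ftype="dispensary", ownership="public", ward_density=100.0,
              golive_date=pd.Timestamp("2018-01-01"))


class TestClassifyVisits:
    @pytest.fixture()
    def setup(self):
        facilities = _geo_fixture()
        patients = pd.DataFrame([{
            "patient_id": "P1", "sex": "female",
            "birth_date": pd.Timestamp("2018-01-01"),
            "assigned_facility_id": "A",
            "registration_date": pd.Timestamp("2018-01-01")}])
        return facilities, patients

    @pytest.mark.parametrize("visited,band", [
        ("A", "assigned"),
        ("B", "within_5km"),
        ("C", "same_district_gt5km"),
        ("D", "same_region_other_district"),
        ("E", "other_region"),  # despite being ~3.4 km away
    ])
    def test_five_way_banding(self, setup, visited, band):
        facilities, patients = setup
        visits = pd.DataFrame([{
            "visit_id": "V1", "patient_id": "P1", "facility_id": visited,
            "visit_date": pd.Timestamp("2018-02-01")}])
        rec = mv.classify_visits(visits, patients, facilities).iloc[0]
        assert rec["band"] == band
        assert rec["nonassigned"] == (band != "assigned")

    def test_missing_geocode_falls_back_to_admin(self, setup):
        facilities, patients = setup
        facilities.loc[facilities["facility_id"] == "B",
                       ["lat", "lon"]] = np.nan
        visits = pd.DataFrame([{
            "visit_id": "V1", "patient_id": "P1", "facility_id": "B",
            "visit_date": pd.Timestamp("2018-02-01")}])
        rec = mv.classify_visits(visits, patients, facilities).iloc[0]
        assert rec["band"] == "same_district_gt5km"
        assert pd.isna(rec["distance_km"])


class TestFacilityDensity:
    def test_matches_brute_force_pairwise(self, small_sim):
        bundle, _ = small_sim
        fac = bundle.facilities
        got = mv.facility_density(fac, 5.0).set_index("facility_id")
        lat, lon = fac["lat"].to_numpy(), fac["lon"].to_numpy()
        for i, fid in enumerate(fac["facility_id"]):
            n = sum(1 for j in range(len(fac)) if j != i
                    and mv.haversine_km(lat[i], lon[i], lat[j], lon[j]) <= 5.0)
            assert got.loc[fid, "n_within_radius"] == n

    def test_isolated_facility_and_band_edges(self):
        fac = _geo_fixture()
        got = mv.facility_density(fac, 5.0).set_index("facility_id")
        assert got.loc["C", "n_within_radius"] == 0
        assert got.loc["A", "n_within_radius"] == 2  # B and E
        assert got.loc["C", "density_band"] == "0"

    @pytest.mark.parametrize("count,band", [
        (0, "0"), (1, "1"), (2, "2-5"), (5, "2-5"), (6, ">5")])
    def test_density_band_edges(self, count, band):
        assert mv.density_band(count) == band


class TestUrbanicity:
    @pytest.mark.parametrize("density,expected", [
        (500.0, "urban"),   # boundary inclusive
        (499.9, "rural"),
        (np.nan, None),
    ])
    def test_threshold(self, density, expected):
        fac = pd.DataFrame({"ward_density": [density]})
        got = mv.derive_urbanicity(fac).iloc[0]
        if expected is None:
            assert pd.isna(got)
        else:
            assert got == expected

    def test_patient_inherits_assigned_facility_urbanicity(self, small_sim):
        bundle, _ = small_sim
        fac = bundle.facilities.copy()
        fac["urbanicity"] = mv.derive_urbanicity(fac)
        lut = fac.set_index("facility_id")["urbanicity"]
        patients = bundle.patients
        inherited = patients["assigned_facility_id"].map(lut)
        assert len(inherited) == len(patients)
        assert set(inherited.dropna().unique()) <= {"urban", "rural"}


class TestMovementTables:
    def test_all_assigned_fixture_zero_percent(self):
        records = pd.DataFrame({
            "visit_id": ["v1", "v2"], "band": ["assigned", "assigned"],
            "nonassigned": [False, False],
            "assigned_facility_id": ["A", "A"]})
        cov = pd.DataFrame({"visit_id": ["v1", "v2"], "sex": ["f", "m"]})
        by_stratum, _ = mv.movement_tables(records, cov, ["sex"])
        assert (by_stratum["pct_nonassigned"] == 0.0).all()

    def test_band_counts_sum_to_total(self, schedule, small_sim):
        bundle, _ = small_sim
        live, _ = clean_bundle(bundle)
        records = mv.classify_visits(live.visits, live.patients,
                                     live.facilities)
        assert records["band"].isin(mv.BANDS).all()
        band_counts = records["band"].value_counts()
        assert band_counts.sum() == len(records)
        assert (records["nonassigned"].sum()
                == band_counts.drop("assigned", errors="ignore").sum())

    def test_movement_rate_recovered(self, schedule):
        cfg = SimConfig(seed=17, n_children=3000, movement_prob=0.06,
                        back_entry_prob=0.0)
        bundle, truth = simulate_registry(cfg)
        live, _ = clean_bundle(bundle)
        records = mv.classify_visits(live.visits, live.patients,
                                     live.facilities)
        n = len(records)
        p = truth.expected_nonassigned_rate
        se = np.sqrt(p * (1 - p) / n)
        assert abs(records["nonassigned"].mean() - p) < 3 * se

    def test_order_invariance(self, small_sim):
        bundle, _ = small_sim
        live, _ = clean_bundle(bundle)
        a = mv.classify_visits(live.visits, live.patients, live.facilities)
        shuffled = live.visits.sample(frac=1, random_state=3)
        b = mv.classify_visits(shuffled, live.patients, live.facilities)
        merged = a.merge(b, on="visit_id", suffixes=("_a", "_b"))
        assert (merged["band_a"] == merged["band_b"]).all()
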