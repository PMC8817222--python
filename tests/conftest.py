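import datetime as dt

import pandas as pd
import pytest

from eirkit.data_model import RegistryBundle, validate_bundle
from eirkit.schedule import default_schedule
from eirkit.synthetic_data import SimConfig, simulate_registry


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated registry with its ground truth (shared read-only)."""
    bundle, truth = simulate_registry(SimConfig(seed=11, n_children=400))
    return bundle, truth


def make_tiny_bundle() -> RegistryBundle:
    """Hand-built four-child registry covering the main record shapes."""
    facilities = pd.DataFrame([
        {"facility_id": "F01", "region": "RA", "district": "RAD1",
         "lat": -6.0, "lon": 35.0, "ftype": "dispensary",
         "ownership": "public", "ward_density": 120.0,
         "golive_date": pd.Timestamp("2017-06-01")},
        {"facility_id": "F02", "region": "RA", "district": "RAD1",
         "lat": -6.02, "lon": 35.01, "ftype": "hospital",
         "ownership": "private", "ward_density": 900.0,
         "golive_date": pd.Timestamp("2018-01-01")},
        {"facility_id": "F03", "region": "RB", "district": "RBD1",
         "lat": -7.5, "lon": 36.0, "ftype": "health_center",
         "ownership": "public", "ward_density": 500.0,
         "golive_date": pd.Timestamp("2018-06-01")},
    ])
    patients = pd.DataFrame([
        {"patient_id": "P1", "sex": "female",
         "birth_date": pd.Timestamp("2018-01-01"),
         "assigned_facility_id": "F01",
         "registration_date": pd.Timestamp("2018-01-01")},
        {"patient_id": "P2", "sex": "male",
         "birth_date": pd.Timestamp("2018-03-01"),
         "assigned_facility_id": "F01",
         "registration_date": pd.Timestamp("2018-03-01")},
        {"patient_id": "P3", "sex": "female",
         "birth_date": pd.Timestamp("2018-05-01"),
         "assigned_facility_id": "F02",
         "registration_date": pd.Timestamp("2018-05-10")},
        {"patient_id": "P4", "sex": "unknown",
         "birth_date": pd.Timestamp("2018-06-01"),
         "assigned_facility_id": "F03",
         "registration_date": pd.Timestamp("2018-06-01")},
    ])
    visits = pd.DataFrame([
        {"visit_id": "V1", "patient_id": "P1", "facility_id": "F01",
         "visit_date": pd.Timestamp("2018-01-01")},
        {"visit_id": "V2", "patient_id": "P1", "facility_id": "F01",
         "visit_date": pd.Timestamp("2018-02-12")},
        {"visit_id": "V3", "patient_id": "P2", "facility_id": "F02",
         "visit_date": pd.Timestamp("2018-03-01")},
        {"visit_id": "V4", "patient_id": "P3", "facility_id": "F02",
         "visit_date": pd.Timestamp("2018-06-12")},
    ])
    doses = pd.DataFrame([
        {"patient_id": "P1", "visit_id": "V1", "vaccine": "BCG",
         "dose_number": 0, "date_given": pd.Timestamp("2018-01-01"),
         "entry_mode": "live", "missed_reason": "none"},
        {"patient_id": "P1", "visit_id": "V1", "vaccine": "OPV",
         "dose_number": 0, "date_given": pd.Timestamp("2018-01-01"),
         "entry_mode": "live", "missed_reason": "none"},
        {"patient_id": "P1", "visit_id": "V2", "vaccine": "Penta",
         "dose_number": 1, "date_given": pd.Timestamp("2018-02-12"),
         "entry_mode": "live", "missed_reason": "none"},
        {"patient_id": "P1", "visit_id": "V2", "vaccine": "Rota",
         "dose_number": 1, "date_given": pd.Timestamp("2018-02-12"),
         "entry_mode": "live", "missed_reason": "stockout"},
        {"patient_id": "P2", "visit_id": "V3", "vaccine": "BCG",
         "dose_number": 0, "date_given": pd.Timestamp("2018-03-01"),
         "entry_mode": "live", "missed_reason": "none"},
        {"patient_id": "P3", "visit_id": "", "vaccine": "BCG",
         "dose_number": 0, "date_given": pd.Timestamp("2018-05-01"),
         "entry_mode": "back_entered", "missed_reason": "none"},
        {"patient_id": "P3", "visit_id": "V4", "vaccine": "Penta",
         "dose_number": 1, "date_given": pd.Timestamp("2018-06-12"),
         "entry_mode": "live", "missed_reason": "none"},
        {"patient_id": "P4", "visit_id": "", "vaccine": "BCG",
         "dose_number": 0, "date_given": pd.Timestamp("2018-06-01"),
         "entry_mode": "back_entered", "missed_reason": "none"},
    ])
    stock = pd.DataFrame([
        {"facility_id": "F01", "vaccine": "BCG",
         "date": pd.Timestamp("2018-01-01"), "balance": 10},
        {"facility_id": "F01", "vaccine": "BCG",
         "date": pd.Timestamp("2018-01-02"), "balance": 0},
        {"facility_id": "F02", "vaccine": "Rota",
         "date": pd.Timestamp("2018-02-12"), "balance": 0},
    ])
    bundle = RegistryBundle(patients=patients, facilities=facilities,
                            visits=visits, doses=doses, stock=stock)
    validate_bundle(bundle)
    return bundle


@pytest.fixture()
def tiny_bundle():
    return make_tiny_bundle()
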