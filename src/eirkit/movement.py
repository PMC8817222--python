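"""Population movement: assigned vs nonassigned visits and distance bands.

Each child has an assigned (home) facility; a nonassigned visit is a
contact at any other facility.  Nonassigned visits are banded by how far
the visited facility is from the assigned one: within 5 km, beyond 5 km
but in the same district, a different district of the same region, or a
different region.  Administrative comparisons take precedence over
distance for the cross-district/region bands; the 5 km boundary is
inclusive.  Assignment, not proximity, defines the reference: a visit to
the assigned facility is band ``assigned`` even if another facility is
closer.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

BANDS = ("assigned", "within_5km", "same_district_gt5km",
         "same_region_other_district", "other_region")

DENSITY_BANDS = ("0", "1", "2-5", ">5")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (vectorized)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = (np.sin(dlat / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def classify_visits(visits: pd.DataFrame, patients: pd.DataFrame,
                    facilities: pd.DataFrame,
                    radius_km: float = 5.0) -> pd.DataFrame:
    """One movement record per visit with band and distance.

    When either facility lacks a geocode the band falls back to the
    administrative comparison alone (a same-district nonassigned visit
    without coordinates is banded ``same_district_gt5km`` with null
    distance).
    """
    fac = facilities.set_index("facility_id")
    df = visits.merge(patients[["patient_id", "assigned_facility_id"]],
                      on="patient_id", how="left")
    for side, col in (("visited", "facility_id"),
                      ("assigned", "assigned_facility_id")):
        for attr in ("lat", "lon", "region", "district"):
            df[f"{side}_{attr}"] = df[col].map(fac[attr])
    df["distance_km"] = haversine_km(df["assigned_lat"], df["assigned_lon"],
                                     df["visited_lat"], df["visited_lon"])
    no_geo = (df[["assigned_lat", "assigned_lon", "visited_lat", "visited_lon"]]
              .isna().any(axis=1))
    df.loc[no_geo, "distance_km"] = np.nan

    same_fac = df["facility_id"] == df["assigned_facility_id"]
    same_region = df["visited_region"] == df["assigned_region"]
    same_district = same_region & (df["visited_district"]
                                   == df["assigned_district"])
    within = df["distance_km"] <= radius_km

    band = np.select(
        [same_fac,
         ~same_region,
         same_region & ~same_district,
         same_district & within.fillna(False)],
        ["assigned", "other_region", "same_region_other_district",
         "within_5km"],
        default="same_district_gt5km")
    out = df[["visit_id", "patient_id", "visit_date", "facility_id",
              "assigned_facility_id", "distance_km"]].copy()
    out = out.rename(columns={"facility_id": "visited_facility_id"})
    out["band"] = band
    out["nonassigned"] = out["band"] != "assigned"
    return out


def facility_density(facilities: pd.DataFrame,
                     radius_km: float = 5.0) -> pd.DataFrame:
    """Per-facility count of *other* geocoded facilities within radius,
    with the reporting band {0, 1, 2-5, >5}.  Facilities without a
    geocode get a null count."""
    geoc = facilities.dropna(subset=["lat", "lon"])
    lat = geoc["lat"].to_numpy(float)
    lon = geoc["lon"].to_numpy(float)
    counts = np.zeros(len(geoc), dtype=int)
    # pairwise great-circle distances; facility counts are small enough
    # that the dense matrix is cheap
    if len(geoc) > 1:
        d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        np.fill_diagonal(d, np.inf)
        counts = (d <= radius_km).sum(axis=1)
    out = facilities[["facility_id"]].copy()
    mapping = dict(zip(geoc["facility_id"], counts))
    out["n_within_radius"] = out["facility_id"].map(mapping).astype("Int64")
    out["density_band"] = out["n_within_radius"].map(density_band)
    return out


def density_band(count) -> Optional[str]:
    if pd.isna(count):
        return None
    count = int(count)
    if count == 0:
        return "0"
    if count == 1:
        return "1"
    if count <= 5:
        return "2-5"
    return ">5"


def derive_urbanicity(facilities: pd.DataFrame,
                      threshold: float = 500.0) -> pd.Series:
    """Urban/rural per facility: urban iff ward population density >=
    threshold persons per km^2 (inclusive); missing density -> NA
    (excluded from urbanicity strata).  Patients inherit urbanicity from
    their assigned facility."""
    dens = facilities["ward_density"]
    out = pd.Series(pd.NA, index=facilities.index, dtype="object")
    out[dens.notna() & (dens >= threshold)] = "urban"
    out[dens.notna() & (dens < threshold)] = "rural"
    out.index = facilities.index
    return out


def eir_duration_band(days) -> Optional[str]:
    """Bin a facility's registry-use duration (days since go-live) into
    the reporting bands 0-5 months, 6-11 months, 1 year, >=2 years."""
    if pd.isna(days):
        return None
    months = days / 30.44
    if months < 6:
        return "0-5 months"
    if months < 12:
        return "6-11 months"
    if months < 24:
        return "1 year"
    return ">=2 years"


def movement_tables(records: pd.DataFrame, covariates: pd.DataFrame,
                    strata: Sequence[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified assigned/nonassigned summaries plus per-region band
    composition among nonassigned visits.

    ``covariates`` has one row per visit_id (patient and assigned-facility
    characteristics).  Returns ``(by_stratum, band_composition)``.
    """
    df = records.merge(covariates, on="visit_id", how="left")
    rows = []
    groups = [("overall", "overall", df)]
    for s in strata:
        if s not in df.columns:
            raise KeyError(f"unknown stratum variable: {s}")
        groups += [(s, str(lev), sub)
                   for lev, sub in df.groupby(s, dropna=True, observed=True)]
    for variable, level, sub in groups:
        n = len(sub)
        na = int(sub["nonassigned"].sum())
        rows.append({"variable": variable, "level": level, "n_visits": n,
                     "n_nonassigned": na,
                     "pct_nonassigned": 100 * na / n if n else np.nan,
                     "n_assigned": n - na,
                     "pct_assigned": 100 * (n - na) / n if n else np.nan})
    by_stratum = pd.DataFrame(rows)

    comp_rows = []
    if "assigned_region" in df.columns:
        nonass = df[df["nonassigned"]]
        for region, sub in nonass.groupby("assigned_region", dropna=True):
            rec = {"region": region, "n_nonassigned": len(sub)}
            for band in BANDS[1:]:
                nb = int((sub["band"] == band).sum())
                rec[f"n_{band}"] = nb
                rec[f"pct_{band}"] = (100 * nb / len(sub)
                                      if len(sub) else np.nan)
            comp_rows.append(rec)
    band_composition = pd.DataFrame(comp_rows)
    return by_stratum, band_composition


def assigned_attendance_by_facility(records: pd.DataFrame) -> pd.DataFrame:
    """Per assigned facility: fraction of its children's visits that
    occurred at the assigned facility (the mapping table behind
    facility-attendance choropleths)."""
    g = records.groupby("assigned_facility_id")
    out = g.agg(n_visits=("visit_id", "size"),
                n_assigned=("nonassigned", lambda s: int((~s).sum())))
    out["pct_assigned"] = 100 * out["n_assigned"] / out["n_visits"]
    return out.reset_index()
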