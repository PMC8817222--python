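"""Registry tables: schemas, delimited-file I/O, validation and cleaning.

The registry is five delimited tables — patients, facilities, visits,
dose records and a stock ledger — mirroring the structure of a national
electronic immunization registry extract.  A single dose table holds both
administered doses and explicitly-missed doses, discriminated by
``missed_reason`` (``none`` iff the dose was administered); this keeps
reason attribution for missed opportunities local to one table.

Cleaning rules implemented here:

* campaign dummy IDs — any patient with more than three records of a
  single (vaccine, dose number) slot is treated as a dummy ID used to log
  mass-campaign vaccinations and removed from all tables;
* duplicate administered records (2-3 repeats of one slot, assumed data
  entry errors) are collapsed to the earliest date given;
* regions with fewer live visits than a threshold by a cutoff date are
  dropped entirely;
* back-entered doses (records typed retroactively to complete a child's
  history) are kept only for continuum-of-care analyses and only for
  patients with at least one live entry.

The canonical cleaning order is exclude_campaign_ids -> restrict_regions
-> filter_live_doses -> dedup_repeat_doses (see :func:`clean_bundle`).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SEX_VALUES = {"female", "male", "unknown"}
FTYPE_VALUES = {"dispensary", "health_center", "hospital"}
OWNERSHIP_VALUES = {"public", "private"}
VACCINE_VALUES = {"BCG", "OPV", "Penta", "PCV", "Rota", "MCV"}
ENTRY_MODE_VALUES = {"live", "back_entered"}
MISSED_REASON_VALUES = {"none", "stockout", "contraindication", "late",
                        "refusal", "expired_stock"}

#: required columns per table; date columns are parsed as ISO dates
SCHEMAS: dict[str, dict] = {
    "patients": {
        "columns": ["patient_id", "sex", "birth_date", "assigned_facility_id",
                    "registration_date"],
        "dates": ["birth_date", "registration_date"],
    },
    "facilities": {
        "columns": ["facility_id", "region", "district", "lat", "lon", "ftype",
                    "ownership", "ward_density", "golive_date"],
        "dates": ["golive_date"],
    },
    "visits": {
        "columns": ["visit_id", "patient_id", "facility_id", "visit_date"],
        "dates": ["visit_date"],
    },
    "doses": {
        "columns": ["patient_id", "visit_id", "vaccine", "dose_number",
                    "date_given", "entry_mode", "missed_reason"],
        "dates": ["date_given"],
    },
    "stock": {
        "columns": ["facility_id", "vaccine", "date", "balance"],
        "dates": ["date"],
    },
}

TABLE_NAMES = tuple(SCHEMAS)


class SchemaError(ValueError):
    """A required column is missing or a file cannot be interpreted."""


class ValidationError(ValueError):
    """Table contents violate a registry invariant (e.g. a foreign key)."""


@dataclass
class RegistryBundle:
    """The five registry tables plus the rejects report from reading."""

    patients: pd.DataFrame
    facilities: pd.DataFrame
    visits: pd.DataFrame
    doses: pd.DataFrame
    stock: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["table", "row", "reason"]))

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def copy(self) -> "RegistryBundle":
        return RegistryBundle(**{n: self.table(n).copy() for n in TABLE_NAMES},
                              rejects=self.rejects.copy())

    @property
    def administered(self) -> pd.DataFrame:
        """Dose records that were actually given (missed_reason == none)."""
        return self.doses[self.doses["missed_reason"] == "none"]

    def counts(self) -> dict[str, int]:
        return {n: len(self.table(n)) for n in TABLE_NAMES}


def _parse_dates(df: pd.DataFrame, cols: Sequence[str],
                 table: str, rejects: list) -> pd.DataFrame:
    bad = pd.Series(False, index=df.index)
    for c in cols:
        parsed = pd.to_datetime(df[c], format="%Y-%m-%d", errors="coerce")
        newly_bad = parsed.isna() & df[c].notna() & (df[c].astype(str) != "")
        bad |= newly_bad
        df[c] = parsed
    for idx in df.index[bad]:
        rejects.append({"table": table, "row": int(idx),
                        "reason": "unparseable date"})
    return df[~bad]


def read_table(path: Path, table: str,
               column_map: Optional[Mapping[str, str]] = None,
               rejects: Optional[list] = None) -> pd.DataFrame:
    """Read one registry table from CSV, applying an optional column
    mapping (schema name -> file column name) and collecting rows with
    unparseable dates into ``rejects`` instead of dropping them silently."""
    schema = SCHEMAS[table]
    df = pd.read_csv(path, dtype=str)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")
    df = df[schema["columns"]].copy()
    local_rejects: list = [] if rejects is None else rejects
    df = _parse_dates(df, schema["dates"], table, local_rejects)
    for col in ("dose_number",):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col]).astype(int)
    for col in ("lat", "lon", "ward_density"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "balance" in df.columns:
        df["balance"] = pd.to_numeric(df["balance"]).astype(int)
    return df.reset_index(drop=True)


def validate_bundle(bundle: RegistryBundle) -> None:
    """Enforce registry invariants; raises :class:`ValidationError`.

    Checks enum domains, foreign keys, coordinate ranges, date ordering
    (birth <= registration, visit >= birth) and stock-row uniqueness.
    """
    p, f, v, d, s = (bundle.patients, bundle.facilities, bundle.visits,
                     bundle.doses, bundle.stock)

    def check_enum(series, allowed, what):
        bad = set(series.dropna().unique()) - allowed
        if bad:
            raise ValidationError(f"invalid {what} value(s): {sorted(bad)}")

    check_enum(p["sex"], SEX_VALUES, "sex")
    check_enum(f["ftype"], FTYPE_VALUES, "facility type")
    check_enum(f["ownership"], OWNERSHIP_VALUES, "ownership")
    check_enum(d["vaccine"], VACCINE_VALUES, "vaccine")
    check_enum(d["entry_mode"], ENTRY_MODE_VALUES, "entry mode")
    check_enum(d["missed_reason"], MISSED_REASON_VALUES, "missed reason")
    check_enum(s["vaccine"], VACCINE_VALUES, "stock vaccine")

    fac_ids = set(f["facility_id"])
    orphans = sorted(set(p["assigned_facility_id"].dropna()) - fac_ids)
    if orphans:
        raise ValidationError(
            f"patients reference unknown assigned facilities: {orphans[:10]}")
    orphans = sorted(set(v["facility_id"].dropna()) - fac_ids)
    if orphans:
        raise ValidationError(f"visits reference unknown facilities: {orphans[:10]}")
    pat_ids = set(p["patient_id"])
    orphans = sorted(set(v["patient_id"]) - pat_ids)
    if orphans:
        raise ValidationError(f"visits reference unknown patients: {orphans[:10]}")
    orphans = sorted(set(d["patient_id"]) - pat_ids)
    if orphans:
        raise ValidationError(f"doses reference unknown patients: {orphans[:10]}")
    visit_ids = set(v["visit_id"])
    linked = d["visit_id"].dropna()
    linked = linked[linked.astype(str) != ""]
    orphans = sorted(set(linked) - visit_ids)
    if orphans:
        raise ValidationError(f"doses reference unknown visits: {orphans[:10]}")

    geoc = f.dropna(subset=["lat", "lon"])
    if ((geoc["lat"].abs() > 90) | (geoc["lon"].abs() > 180)).any():
        raise ValidationError("facility coordinates out of range")
    dens = f["ward_density"].dropna()
    if (dens < 0).any():
        raise ValidationError("negative ward density")
    # strict nesting: a district name belongs to exactly one region
    nest = f.groupby("district")["region"].nunique()
    if (nest > 1).any():
        raise ValidationError(
            f"district(s) span multiple regions: {list(nest[nest > 1].index)[:10]}")

    reg = p.dropna(subset=["birth_date", "registration_date"])
    if (reg["birth_date"] > reg["registration_date"]).any():
        raise ValidationError("birth date after registration date")
    vb = v.merge(p[["patient_id", "birth_date"]], on="patient_id", how="left")
    if (vb["visit_date"] < vb["birth_date"]).any():
        raise ValidationError("visit predates patient birth date")
    if s.duplicated(["facility_id", "vaccine", "date"]).any():
        raise ValidationError("duplicate stock rows for a facility-vaccine-day")


def read_registry(paths: Mapping[str, Path],
                  config: Optional[Mapping] = None) -> RegistryBundle:
    """Read and validate all five registry tables.

    ``paths`` maps table name -> file path.  ``config`` may carry
    ``column_map`` ({table: {schema column: file column}}).  Unparseable
    rows are collected into ``bundle.rejects`` with a reason, never
    silently dropped.
    """
    config = dict(config or {})
    column_map = config.get("column_map", {})
    rejects: list = []
    tables = {}
    for name in TABLE_NAMES:
        tables[name] = read_table(Path(paths[name]), name,
                                  column_map.get(name), rejects)
    bundle = RegistryBundle(
        **tables, rejects=pd.DataFrame(rejects, columns=["table", "row", "reason"]))
    validate_bundle(bundle)
    return bundle


def write_registry(bundle: RegistryBundle, out_dir: Path) -> dict[str, Path]:
    """Write all tables as UTF-8 CSV with ISO dates; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in TABLE_NAMES:
        df = bundle.table(name).copy()
        for c in SCHEMAS[name]["dates"]:
            df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    if len(bundle.rejects):
        paths["rejects"] = out_dir / "rejects.csv"
        bundle.rejects.to_csv(paths["rejects"], index=False)
    return paths


def exclude_campaign_ids(doses: pd.DataFrame) -> tuple[pd.DataFrame, set[str]]:
    """Remove campaign dummy patient IDs from the dose table.

    A patient with more than three administered records of any single
    (vaccine, dose_number) slot is assumed to be a dummy ID under which
    mass-campaign vaccinations were logged; all of that patient's rows are
    removed.  Patients with 2-3 repeats of a slot (data entry errors) are
    retained, as are repeated explicitly-missed records (a dose can be
    knowingly withheld at many visits).  Returns the filtered table and
    the excluded patient IDs.
    """
    if doses.empty:
        return doses.copy(), set()
    admin = doses[doses["missed_reason"] == "none"]
    counts = admin.groupby(["patient_id", "vaccine", "dose_number"]).size()
    excluded = set(counts[counts > 3].index.get_level_values("patient_id"))
    return doses[~doses["patient_id"].isin(excluded)].copy(), excluded


def apply_patient_exclusion(bundle: RegistryBundle,
                            excluded: set[str]) -> RegistryBundle:
    """Drop excluded patients from every table of the bundle."""
    out = bundle.copy()
    out.patients = out.patients[~out.patients["patient_id"].isin(excluded)]
    out.visits = out.visits[~out.visits["patient_id"].isin(excluded)]
    out.doses = out.doses[~out.doses["patient_id"].isin(excluded)]
    return out


def dedup_repeat_doses(doses: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated administered records of one dose slot to the
    earliest ``date_given`` (first administration is the immunologically
    relevant event); ties broken by stable input order.  Explicitly-missed
    records are left untouched."""
    if doses.empty:
        return doses.copy()
    admin = doses[doses["missed_reason"] == "none"]
    keep = (admin.reset_index()
            .sort_values(["patient_id", "vaccine", "dose_number", "date_given",
                          "index"], kind="stable")
            .drop_duplicates(["patient_id", "vaccine", "dose_number"],
                             keep="first")["index"])
    missed_idx = doses.index[doses["missed_reason"] != "none"]
    kept = doses.loc[sorted(set(keep) | set(missed_idx))]
    return kept.copy()


def restrict_regions(bundle: RegistryBundle, min_visits: int,
                     cutoff_date: dt.date) -> tuple[RegistryBundle, set[str]]:
    """Drop regions with fewer than ``min_visits`` visits recorded by
    ``cutoff_date`` from every table.  Returns (bundle, dropped regions)."""
    cutoff = pd.Timestamp(cutoff_date)
    v = bundle.visits.merge(bundle.facilities[["facility_id", "region"]],
                            on="facility_id", how="left")
    counts = v.loc[v["visit_date"] <= cutoff].groupby("region").size()
    all_regions = set(bundle.facilities["region"])
    keep_regions = {r for r in all_regions if counts.get(r, 0) >= min_visits}
    dropped = all_regions - keep_regions
    if not dropped:
        return bundle.copy(), dropped

    out = bundle.copy()
    out.facilities = out.facilities[out.facilities["region"].isin(keep_regions)]
    fac_ids = set(out.facilities["facility_id"])
    out.patients = out.patients[out.patients["assigned_facility_id"].isin(fac_ids)]
    pat_ids = set(out.patients["patient_id"])
    out.visits = out.visits[out.visits["facility_id"].isin(fac_ids)
                            & out.visits["patient_id"].isin(pat_ids)]
    out.doses = out.doses[out.doses["patient_id"].isin(pat_ids)]
    out.stock = out.stock[out.stock["facility_id"].isin(fac_ids)]
    return out, dropped


def filter_live_doses(doses: pd.DataFrame,
                      include_back_entered: bool = False) -> pd.DataFrame:
    """Restrict the dose table by entry mode.

    With ``include_back_entered=False`` only live entries are kept.  With
    ``True`` (continuum-of-care mode) back-entered rows are also kept, but
    only for patients who have at least one live record — patients known
    to the system only through retroactive data entry are excluded.
    """
    live = doses["entry_mode"] == "live"
    if not include_back_entered:
        return doses[live].copy()
    live_patients = set(doses.loc[live, "patient_id"])
    return doses[doses["patient_id"].isin(live_patients)].copy()


@dataclass
class CleaningLog:
    excluded_campaign_ids: set[str] = field(default_factory=set)
    dropped_regions: set[str] = field(default_factory=set)
    counts_before: dict = field(default_factory=dict)
    counts_after: dict = field(default_factory=dict)


def clean_bundle(bundle: RegistryBundle, *, min_region_visits: int = 0,
                 cutoff_date: Optional[dt.date] = None,
                 include_back_entered: bool = False,
                 ) -> tuple[RegistryBundle, CleaningLog]:
    """Apply the full cleaning pipeline in canonical order:
    campaign-ID exclusion, region restriction, entry-mode filter, dedup."""
    log = CleaningLog(counts_before=bundle.counts())
    _, excluded = exclude_campaign_ids(bundle.doses)
    out = apply_patient_exclusion(bundle, excluded)
    log.excluded_campaign_ids = excluded
    if min_region_visits > 0:
        if cutoff_date is None:
            raise ValueError("cutoff_date required when min_region_visits > 0")
        out, dropped = restrict_regions(out, min_region_visits, cutoff_date)
        log.dropped_regions = dropped
    if include_back_entered:
        # back-entered-only patients leave the analysis population
        # entirely; zero-dose patients (no dose records at all) stay
        has_dose = set(out.doses["patient_id"])
        kept = set(filter_live_doses(out.doses, True)["patient_id"])
        only_back = has_dose - kept
        out.patients = out.patients[
            ~out.patients["patient_id"].isin(only_back)]
        out.visits = out.visits[~out.visits["patient_id"].isin(only_back)]
    out.doses = filter_live_doses(out.doses, include_back_entered)
    out.doses = dedup_repeat_doses(out.doses)
    log.counts_after = out.counts()
    return out, log
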