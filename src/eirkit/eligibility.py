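"""Per-visit dose eligibility and missed-opportunity (MOV) detection.

A missed opportunity for vaccination is any contact with the health
system at which the child was eligible for one or more doses but did not
receive them.  Eligibility at a visit is decided from the child's age,
the doses already received strictly before the visit, and the time since
the previous dose of the same vaccine sequence:

* the child must be at or above the dose's minimum age and at or below
  its maximum age (rotavirus doses are never eligible after the first
  year of life);
* the previous dose of the sequence must have been received at least the
  minimum interval (default 28 days) before the visit — unless the dose
  is a sequence start;
* OPV-1 is additionally a valid sequence start when the OPV birth dose
  was never received and its birth-dose window has closed;
* a dose already received is never eligible again.

Doses withheld for a medical contraindication count as MOVs (with reason
``contraindication``), matching how registry reasons are tabulated; a
strict-WHO mode that excludes them is available via ``strict_who``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .schedule import Schedule, ScheduleDose

DoseKey = tuple[str, int]


@dataclass
class VisitAssessment:
    """Eligibility outcome of one health-system contact."""

    visit_id: str
    patient_id: str
    facility_id: str
    visit_date: dt.date
    age_at_visit_days: int
    eligible_doses: frozenset[DoseKey]
    given_doses: frozenset[DoseKey]
    reasons: dict[DoseKey, str] = field(default_factory=dict)

    @property
    def missed_doses(self) -> frozenset[DoseKey]:
        return self.eligible_doses - self.given_doses

    @property
    def mov_count(self) -> int:
        return len(self.missed_doses)

    @property
    def mov_any(self) -> bool:
        return self.mov_count > 0


def eligible_at(schedule: Schedule,
                history: Mapping[DoseKey, dt.date],
                birth_date: dt.date,
                visit_date: dt.date,
                strict_who: bool = False,
                contraindicated: Iterable[DoseKey] = ()) -> set[DoseKey]:
    """Set of (vaccine, dose_number) the child is eligible for at a visit.

    ``history`` maps dose -> date given for doses received strictly
    before ``visit_date`` (same-day doses belong to the visit itself).
    With ``strict_who=True``, doses listed in ``contraindicated`` are not
    counted as eligible.
    """
    if visit_date < birth_date:
        raise ValueError("visit predates birth")
    age = (visit_date - birth_date).days
    contra = set(contraindicated) if strict_who else set()
    out: set[DoseKey] = set()
    for dose in schedule.doses:
        key = dose.key
        if key in history or key in contra:
            continue
        if age < dose.min_age_days:
            continue
        if dose.max_age_days is not None and age > dose.max_age_days:
            continue
        prev = schedule.previous_dose(dose)
        if prev is None:
            out.add(key)
            continue
        prev_date = history.get(prev.key)
        if prev_date is not None:
            if (visit_date - prev_date).days >= dose.min_interval_days:
                out.add(key)
        elif dose.vaccine == "OPV" and dose.dose_number == 1:
            # birth-dose window closed without OPV-0: OPV-1 starts the sequence
            if age > schedule.opv0_window_days:
                out.add(key)
    return out


def assess_visit(schedule: Schedule, *, visit_id: str, patient_id: str,
                 facility_id: str, birth_date: dt.date, visit_date: dt.date,
                 doses_given: Iterable[DoseKey],
                 missed_records: Optional[Mapping[DoseKey, str]] = None,
                 history: Optional[Mapping[DoseKey, dt.date]] = None,
                 strict_who: bool = False) -> VisitAssessment:
    """Assess one visit: eligible vs given doses, MOV flags and reasons.

    ``missed_records`` maps doses explicitly logged as not given to their
    recorded reason; eligible doses missed without a record get reason
    ``none`` (the reason is only noted when a dose is knowingly withheld).
    """
    history = dict(history or {})
    missed_records = dict(missed_records or {})
    eligible = eligible_at(schedule, history, birth_date, visit_date,
                           strict_who=strict_who,
                           contraindicated=[k for k, r in missed_records.items()
                                            if r == "contraindication"])
    given = frozenset(doses_given)
    reasons = {key: missed_records.get(key, "none")
               for key in eligible - given}
    return VisitAssessment(
        visit_id=visit_id, patient_id=patient_id, facility_id=facility_id,
        visit_date=visit_date,
        age_at_visit_days=(visit_date - birth_date).days,
        eligible_doses=frozenset(eligible), given_doses=given, reasons=reasons)


def assess_bundle(bundle, schedule: Schedule,
                  strict_who: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assess every immunization-system contact in a registry bundle.

    Same-day visits by one patient are merged into a single contact (one
    assessment per patient-day; the first visit row provides the ID and
    facility).  Only administered doses dated strictly before the contact
    form the history; administered doses dated on the contact day count
    as given at it, whether or not their visit link matches.

    Returns ``(assessments, missed)``:

    * ``assessments`` — one row per contact with patient/facility IDs,
      date, age, eligible/given/missed counts, ``mov_any`` and one
      ``mov_<vaccine>`` flag per vaccine;
    * ``missed`` — one row per missed dose with its attributed reason.
    """
    patients = bundle.patients.set_index("patient_id")
    admin = bundle.administered
    explicit_missed = bundle.doses[bundle.doses["missed_reason"] != "none"]

    admin_by_patient: dict[str, list] = {}
    for row in admin.itertuples():
        admin_by_patient.setdefault(row.patient_id, []).append(
            (row.date_given, row.vaccine, int(row.dose_number)))
    missed_by_pv: dict[tuple[str, pd.Timestamp], dict] = {}
    missed_visits = explicit_missed.merge(
        bundle.visits[["visit_id", "visit_date"]], on="visit_id", how="left")
    for row in missed_visits.itertuples():
        date = row.visit_date if pd.notna(row.visit_date) else row.date_given
        missed_by_pv.setdefault((row.patient_id, date), {})[
            (row.vaccine, int(row.dose_number))] = row.missed_reason

    vaccines = sorted({d.vaccine for d in schedule.doses})
    rows = []
    missed_rows = []
    visits = bundle.visits.sort_values(["patient_id", "visit_date", "visit_id"],
                                       kind="stable")
    for patient_id, group in visits.groupby("patient_id", sort=False):
        birth = patients.loc[patient_id, "birth_date"]
        recs = sorted(admin_by_patient.get(patient_id, []),
                      key=lambda r: r[0])
        for visit_date, day in group.groupby("visit_date", sort=True):
            history = {(v, n): d for d, v, n in recs if d < visit_date}
            given = {(v, n) for d, v, n in recs if d == visit_date}
            mr = missed_by_pv.get((patient_id, visit_date), {})
            a = assess_visit(
                schedule, visit_id=day.iloc[0]["visit_id"],
                patient_id=patient_id, facility_id=day.iloc[0]["facility_id"],
                birth_date=birth, visit_date=visit_date,
                doses_given=given, missed_records=mr, history=history,
                strict_who=strict_who)
            rec = {
                "visit_id": a.visit_id, "patient_id": patient_id,
                "facility_id": a.facility_id, "visit_date": visit_date,
                "age_at_visit_days": a.age_at_visit_days,
                "n_eligible": len(a.eligible_doses),
                "n_given": len(a.given_doses & a.eligible_doses),
                "mov_count": a.mov_count, "mov_any": a.mov_any,
            }
            missed_vaccines = {v for v, _ in a.missed_doses}
            for v in vaccines:
                rec[f"mov_{v}"] = v in missed_vaccines
            rows.append(rec)
            for (v, n) in sorted(a.missed_doses):
                missed_rows.append({
                    "visit_id": a.visit_id, "patient_id": patient_id,
                    "facility_id": a.facility_id, "visit_date": visit_date,
                    "vaccine": v, "dose_number": n,
                    "reason": a.reasons[(v, n)]})
    assessments = pd.DataFrame(rows)
    missed = pd.DataFrame(missed_rows, columns=[
        "visit_id", "patient_id", "facility_id", "visit_date", "vaccine",
        "dose_number", "reason"])
    return assessments, missed


def mov_tables(assessments: pd.DataFrame, covariates: pd.DataFrame,
               strata: Sequence[str]) -> pd.DataFrame:
    """Visits-with-MOV counts and percentages by stratum and vaccine.

    ``covariates`` carries one row per visit_id with the stratification
    variables.  Output: one row per (stratum variable, level) plus an
    overall row, with total visits, any-MOV count/percent and one
    count/percent pair per vaccine.  Vaccine-specific columns need not
    sum to the any-MOV column (a visit can miss several vaccines).
    """
    df = assessments.merge(covariates, on="visit_id", how="left")
    unknown = [s for s in strata if s not in df.columns]
    if unknown:
        raise KeyError(f"unknown stratum variable(s): {unknown}")
    vaccines = sorted(c[len("mov_"):] for c in assessments.columns
                      if c.startswith("mov_") and c != "mov_any"
                      and c != "mov_count")

    def summarize(sub: pd.DataFrame, variable: str, level: str) -> dict:
        n = len(sub)
        rec = {"variable": variable, "level": level, "n_visits": n,
               "n_mov_any": int(sub["mov_any"].sum()),
               "pct_mov_any": 100 * sub["mov_any"].mean() if n else np.nan}
        for v in vaccines:
            rec[f"n_mov_{v}"] = int(sub[f"mov_{v}"].sum())
            rec[f"pct_mov_{v}"] = 100 * sub[f"mov_{v}"].mean() if n else np.nan
        return rec

    rows = [summarize(df, "overall", "overall")]
    for s in strata:
        for level, sub in df.groupby(s, dropna=True, observed=True):
            rows.append(summarize(sub, s, str(level)))
    return pd.DataFrame(rows)


def mov_reason_table(missed: pd.DataFrame) -> pd.DataFrame:
    """Missed-dose counts per (vaccine, reason), with an overall row.

    Row totals equal each vaccine's recorded MOV count; doses missed
    without an explicit record appear under reason ``none``.
    """
    reasons = ["stockout", "contraindication", "late", "refusal",
               "expired_stock", "none"]
    rows = []
    groups = [("Overall", missed)] + [
        (v, sub) for v, sub in missed.groupby("vaccine")]
    for label, sub in groups:
        rec = {"vaccine": label, "n_mov": len(sub)}
        for r in reasons:
            n = int((sub["reason"] == r).sum())
            rec[f"n_{r}"] = n
            rec[f"pct_{r}"] = 100 * n / len(sub) if len(sub) else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def per_child_mov_summary(assessments: pd.DataFrame
                          ) -> tuple[pd.DataFrame, dict]:
    """Per-child MOV totals and aggregate mean/SD.

    Returns (per-child table with total MOVs and >=1 / >=2 flags, and a
    dict with mean, SD (population), and the shares of children with at
    least one and at least two MOVs).
    """
    per_child = (assessments.groupby("patient_id")["mov_count"].sum()
                 .rename("total_movs").reset_index())
    per_child["ge1"] = per_child["total_movs"] >= 1
    per_child["ge2"] = per_child["total_movs"] >= 2
    totals = per_child["total_movs"]
    agg = {
        "n_children": len(per_child),
        "mean_movs": float(totals.mean()) if len(per_child) else np.nan,
        "sd_movs": float(totals.std(ddof=1)) if len(per_child) > 1 else np.nan,
        "pct_ge1": 100 * per_child["ge1"].mean() if len(per_child) else np.nan,
        "pct_ge2": 100 * per_child["ge2"].mean() if len(per_child) else np.nan,
    }
    return per_child, agg
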