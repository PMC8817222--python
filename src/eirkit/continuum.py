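"""Continuum of care: coverage, timeliness, dropout and typologies.

Works on per-child "cards" — consolidated dose histories for a birth
cohort defined by age at a census date.  Dropout follows the
first-versus-last-dose convention: a child who received the first dose
of a sequence but not its last dropped out of that sequence, regardless
of intermediate doses.  OPV can start at either the birth dose (OPV-0)
or OPV-1 (children who missed the birth-dose window start the sequence
directly at OPV-1), so either counts as starting the sequence.

The immunization typology is the binary received/not-received pattern
over the 14 first-year doses, serialized as a 14-character string of
'R'/'N' in the fixed column order BCG-0, OPV-0..3, Penta-1..3, PCV-1..3,
Rota-1..2, MCV-1.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .schedule import DAYS_PER_MONTH, Schedule, is_timely

#: fixed typology column order over the 14 first-year doses
TYPOLOGY_ORDER: tuple[tuple[str, int], ...] = (
    ("BCG", 0), ("OPV", 0), ("OPV", 1), ("OPV", 2), ("OPV", 3),
    ("Penta", 1), ("Penta", 2), ("Penta", 3),
    ("PCV", 1), ("PCV", 2), ("PCV", 3),
    ("Rota", 1), ("Rota", 2), ("MCV", 1))

DROPOUT_COLUMNS = ("dropout_penta", "dropout_pcv", "dropout_rota",
                   "dropout_opv", "dropout_birth_to_first", "dropout_overall")


def _col(vaccine: str, dose: int, what: str) -> str:
    return f"{what}_{vaccine}_{dose}"


def build_cards(bundle, schedule: Schedule, census_date: dt.date,
                age_min_months: int = 12, age_max_months: int = 47,
                timeliness_window_days: int = 7) -> pd.DataFrame:
    """One consolidated card per cohort child.

    The cohort is children aged [age_min_months, age_max_months] at the
    census date, with age in months computed as floor(age in days /
    days-per-month constant).  The bundle should already include
    back-entered doses (continuum cleaning mode) so cards reflect the
    full vaccine history.
    """
    census = pd.Timestamp(census_date)
    patients = bundle.patients.copy()
    age_days = (census - patients["birth_date"]).dt.days
    patients["age_months_at_census"] = np.floor(
        age_days / DAYS_PER_MONTH).astype("Int64")
    cohort = patients[(patients["age_months_at_census"] >= age_min_months)
                      & (patients["age_months_at_census"] <= age_max_months)]

    admin = bundle.administered
    admin = admin[admin["patient_id"].isin(set(cohort["patient_id"]))]
    first_dates = (admin.sort_values("date_given", kind="stable")
                   .drop_duplicates(["patient_id", "vaccine", "dose_number"])
                   .set_index(["patient_id", "vaccine", "dose_number"])
                   ["date_given"])

    cards = cohort[["patient_id", "sex", "birth_date", "assigned_facility_id",
                    "age_months_at_census"]].reset_index(drop=True).copy()
    births = cards.set_index("patient_id")["birth_date"]
    for dose in schedule.doses:
        v, n = dose.key
        rec_col, date_col, timely_col = (_col(v, n, "received"),
                                         _col(v, n, "date"),
                                         _col(v, n, "timely"))
        dates = cards["patient_id"].map(
            lambda p, v=v, n=n: first_dates.get((p, v, n), pd.NaT))
        cards[date_col] = pd.to_datetime(dates)
        cards[rec_col] = cards[date_col].notna()
        timely = []
        for pid, d in zip(cards["patient_id"], cards[date_col]):
            if pd.isna(d):
                timely.append(False)
            else:
                timely.append(is_timely(schedule, births[pid], d, v, n,
                                        window_days=timeliness_window_days))
        cards[timely_col] = timely

    fy = [d.key for d in schedule.first_year_doses]
    rec = cards[[_col(v, n, "received") for v, n in fy]]
    cards["n_first_year_doses"] = rec.sum(axis=1)
    cards["fully_immunized_14"] = rec.all(axis=1)
    cards["full_except_mcv1"] = ((cards["n_first_year_doses"] == 13)
                                 & ~cards[_col("MCV", 1, "received")])
    cards["zero_dose"] = cards["n_first_year_doses"] == 0
    cards["typology_key"] = ["".join("R" if r else "N" for r in row)
                             for row in cards[[_col(v, n, "received")
                                               for v, n in TYPOLOGY_ORDER]
                                              ].itertuples(index=False)]
    for name, flags in dropout_flags(cards).items():
        cards[name] = flags
    return cards


def dropout_flags(cards: pd.DataFrame) -> dict[str, pd.Series]:
    """The six dropout indicators, computed from received flags.

    A child who never received the starting dose of a sequence is not a
    dropout for it (never started); denominators for vaccine-specific
    rates are therefore children with the starting dose.
    """
    def rec(v, n):
        return cards[_col(v, n, "received")]

    any_dose = cards["n_first_year_doses"] >= 1
    return {
        "dropout_penta": rec("Penta", 1) & ~rec("Penta", 3),
        "dropout_pcv": rec("PCV", 1) & ~rec("PCV", 3),
        "dropout_rota": rec("Rota", 1) & ~rec("Rota", 2),
        "dropout_opv": (rec("OPV", 0) | rec("OPV", 1)) & ~rec("OPV", 3),
        "dropout_birth_to_first": (
            (rec("BCG", 0) | rec("OPV", 0))
            & ~(rec("OPV", 1) | rec("Penta", 1) | rec("PCV", 1) | rec("Rota", 1))),
        "dropout_overall": any_dose & ~cards["fully_immunized_14"],
    }


#: starting-dose denominator definition per dropout flag
DROPOUT_DENOMINATORS = {
    "dropout_penta": lambda c: c[_col("Penta", 1, "received")],
    "dropout_pcv": lambda c: c[_col("PCV", 1, "received")],
    "dropout_rota": lambda c: c[_col("Rota", 1, "received")],
    "dropout_opv": lambda c: c[_col("OPV", 0, "received")]
    | c[_col("OPV", 1, "received")],
    "dropout_birth_to_first": lambda c: c[_col("BCG", 0, "received")]
    | c[_col("OPV", 0, "received")],
    "dropout_overall": lambda c: c["n_first_year_doses"] >= 1,
}


def dropout_table(cards: pd.DataFrame,
                  strata: Sequence[str] = ()) -> pd.DataFrame:
    """Dropout counts/rates per flag, overall and by stratum, using the
    starting-dose denominators."""
    rows = []
    groups = [("overall", "overall", cards)]
    for s in strata:
        groups += [(s, str(lev), sub)
                   for lev, sub in cards.groupby(s, dropna=True, observed=True)]
    for variable, level, sub in groups:
        rec = {"variable": variable, "level": level, "n_children": len(sub)}
        for flag in DROPOUT_COLUMNS:
            den = DROPOUT_DENOMINATORS[flag](sub)
            num = sub[flag]
            rec[f"n_{flag}"] = int(num.sum())
            rec[f"den_{flag}"] = int(den.sum())
            rec[f"pct_{flag}"] = (100 * num.sum() / den.sum()
                                  if den.sum() else np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)


def coverage_timeliness(cards: pd.DataFrame, schedule: Schedule) -> pd.DataFrame:
    """Per-dose coverage (% of cohort with the dose) and timeliness
    (% of received doses given within the grace window)."""
    n = len(cards)
    rows = []
    for dose in schedule.first_year_doses:
        v, dn = dose.key
        received = cards[_col(v, dn, "received")]
        timely = cards[_col(v, dn, "timely")]
        n_rec = int(received.sum())
        rows.append({
            "vaccine": v, "dose_number": dn, "n_cohort": n,
            "n_received": n_rec,
            "coverage_pct": 100 * n_rec / n if n else np.nan,
            "n_timely": int(timely.sum()),
            "timely_pct": 100 * timely.sum() / n_rec if n_rec else np.nan,
        })
    return pd.DataFrame(rows)


def visit_touchpoints(cards: pd.DataFrame, schedule: Schedule) -> pd.DataFrame:
    """Fraction of the cohort reaching each scheduled visit 1-5.

    A visit is reached iff at least one of its scheduled doses was
    received (e.g. visit 1 = either birth dose).
    """
    n = len(cards)
    rows = []
    for k in range(1, 6):
        cols = [_col(v, dn, "received")
                for (v, dn) in (d.key for d in schedule.doses_for_visit(k))]
        reached = cards[cols].any(axis=1)
        rows.append({"visit_number": k, "n_cohort": n,
                     "n_reached": int(reached.sum()),
                     "pct_reached": 100 * reached.mean() if n else np.nan})
    return pd.DataFrame(rows)


def typology_table(cards: pd.DataFrame,
                   top_k: Optional[int] = 10) -> pd.DataFrame:
    """Ranked immunization archetypes.

    Groups children by their 14-dose R/N key, ranks by count (ties broken
    by key for determinism) and returns the top ``top_k`` (all keys when
    None).  Percentages are over the full cohort, so counts over all keys
    sum to cohort size.
    """
    n = len(cards)
    counts = (cards.groupby("typology_key").size().rename("n_children")
              .reset_index()
              .sort_values(["n_children", "typology_key"],
                           ascending=[False, True], kind="stable")
              .reset_index(drop=True))
    counts["pct_children"] = 100 * counts["n_children"] / n if n else np.nan
    counts["rank"] = np.arange(1, len(counts) + 1)
    if top_k is not None:
        counts = counts.head(top_k)
    return counts
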