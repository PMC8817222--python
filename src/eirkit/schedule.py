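"""National infant vaccine schedule and timeliness rules.

The schedule covers six vaccines across six scheduled visits in the first
18 months of life: BCG and OPV-0 at birth, three follow-up visits at
6/10/14 weeks (OPV, Penta, PCV, Rota), measles (MCV-1) at 9 months and
MCV-2 at 18 months.  The "full 14-dose schedule" is everything through
MCV-1, i.e. all doses scheduled in the first year of life.

Month-valued scheduled ages are converted to days with a fixed
days-per-month constant (default 30.44) and rounded, so that scheduled
dates and timeliness do not depend on the calendar month of birth.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import yaml

VACCINES = ("BCG", "OPV", "Penta", "PCV", "Rota", "MCV")

#: days-per-month constant used to convert month-valued scheduled ages
DAYS_PER_MONTH = 30.44

#: default grace window (days) after the scheduled date within which a
#: dose still counts as timely; beyond it the child is a defaulter
TIMELINESS_WINDOW_DAYS = 7

#: default minimum interval (days) between successive doses of a sequence
DEFAULT_MIN_INTERVAL_DAYS = 28

#: window (days) within which the OPV birth dose can still be given;
#: after it the child starts the OPV sequence at OPV-1 directly
DEFAULT_OPV0_WINDOW_DAYS = 14

#: upper age limit (days) of standard eligibility, 5 years
DEFAULT_MAX_AGE_DAYS = 5 * 365


class ScheduleError(ValueError):
    """Raised for ill-formed schedule configurations."""


@dataclass(frozen=True)
class ScheduleDose:
    """One dose slot in the national schedule.

    ``min_age_days`` is the earliest age at which the dose may be given
    (defaults to its scheduled age: a child is never eligible early);
    ``max_age_days`` is the latest (None = unbounded within the standard
    5-year eligibility limit).  ``min_interval_days`` applies from the
    previous dose of the same vaccine sequence and is 0 for a sequence
    start.
    """

    vaccine: str
    dose_number: int
    visit_number: int
    scheduled_age_days: int
    min_age_days: int
    max_age_days: Optional[int]
    min_interval_days: int

    @property
    def key(self) -> tuple[str, int]:
        return (self.vaccine, self.dose_number)

    @property
    def label(self) -> str:
        return f"{self.vaccine}-{self.dose_number}"


@dataclass(frozen=True)
class Schedule:
    """Ordered collection of schedule doses.

    ``doses`` holds all 15 defined doses (through MCV-2); the
    ``first_year_doses`` property is the 14-dose under-12-month set that
    ends at MCV-1 and defines full immunization.
    """

    doses: tuple[ScheduleDose, ...]
    opv0_window_days: int = DEFAULT_OPV0_WINDOW_DAYS

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for d in self.doses:
            if d.key in seen:
                raise ScheduleError(f"duplicate dose {d.label}")
            seen.add(d.key)
        for v in VACCINES:
            seq = self.sequence(v)
            nums = [d.dose_number for d in seq]
            ages = [d.scheduled_age_days for d in seq]
            if nums != sorted(nums) or len(set(nums)) != len(nums):
                raise ScheduleError(f"{v} dose numbers not strictly increasing")
            if ages != sorted(ages) or len(set(ages)) != len(ages):
                raise ScheduleError(f"{v} scheduled ages not strictly increasing")

    def sequence(self, vaccine: str) -> tuple[ScheduleDose, ...]:
        return tuple(d for d in self.doses if d.vaccine == vaccine)

    def dose(self, vaccine: str, dose_number: int) -> ScheduleDose:
        for d in self.doses:
            if d.vaccine == vaccine and d.dose_number == dose_number:
                return d
        raise KeyError(f"{vaccine}-{dose_number} not in schedule")

    def __contains__(self, key: tuple[str, int]) -> bool:
        return any(d.key == key for d in self.doses)

    def doses_for_visit(self, visit_number: int) -> tuple[ScheduleDose, ...]:
        return tuple(d for d in self.doses if d.visit_number == visit_number)

    @property
    def first_year_doses(self) -> tuple[ScheduleDose, ...]:
        """The 14-dose set through MCV-1 (excludes MCV-2)."""
        return tuple(d for d in self.doses if not (d.vaccine == "MCV" and d.dose_number == 2))

    def previous_dose(self, dose: ScheduleDose) -> Optional[ScheduleDose]:
        seq = self.sequence(dose.vaccine)
        idx = seq.index(dose)
        return seq[idx - 1] if idx > 0 else None

    def is_sequence_start(self, dose: ScheduleDose) -> bool:
        return self.previous_dose(dose) is None

    def to_yaml(self) -> str:
        payload = {
            "opv0_window_days": self.opv0_window_days,
            "doses": [
                {
                    "vaccine": d.vaccine,
                    "dose_number": d.dose_number,
                    "visit_number": d.visit_number,
                    "scheduled_age_days": d.scheduled_age_days,
                    "min_age_days": d.min_age_days,
                    "max_age_days": d.max_age_days,
                    "min_interval_days": d.min_interval_days,
                }
                for d in self.doses
            ],
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "Schedule":
        payload = yaml.safe_load(text)
        doses = tuple(ScheduleDose(**row) for row in payload["doses"])
        return cls(doses=doses, opv0_window_days=payload.get(
            "opv0_window_days", DEFAULT_OPV0_WINDOW_DAYS))


def load_shipped_schedule() -> Schedule:
    """Load the packaged default schedule YAML (equals
    ``default_schedule()`` with no overrides)."""
    from importlib import resources
    text = (resources.files("eirkit") / "data" / "default_schedule.yaml"
            ).read_text()
    return Schedule.from_yaml(text)


def _months_to_days(months: float, days_per_month: float) -> int:
    return int(round(months * days_per_month))


def default_schedule(config: Optional[Mapping] = None) -> Schedule:
    """Build the national schedule, optionally overriding visit ages.

    ``config`` keys (all optional): ``visit_age_days`` (mapping visit
    number -> age in days), ``days_per_month``, ``min_interval_days``,
    ``opv0_window_days``, ``bcg_max_age_days``, ``rota_max_age_days``,
    ``max_age_days``.

    Default scheduled ages: birth, 6 weeks (42 d), 10 weeks (70 d),
    14 weeks (98 d), 9 months (274 d) and 18 months (548 d), with the
    month conversions using the fixed days-per-month constant.
    """
    config = dict(config or {})
    dpm = float(config.get("days_per_month", DAYS_PER_MONTH))
    interval = int(config.get("min_interval_days", DEFAULT_MIN_INTERVAL_DAYS))
    opv0_window = int(config.get("opv0_window_days", DEFAULT_OPV0_WINDOW_DAYS))
    max_age = config.get("max_age_days", DEFAULT_MAX_AGE_DAYS)
    bcg_max = config.get("bcg_max_age_days", max_age)
    rota_max = int(config.get("rota_max_age_days", 364))

    visit_ages = {
        1: 0,
        2: 42,
        3: 70,
        4: 98,
        5: _months_to_days(9, dpm),
        6: _months_to_days(18, dpm),
    }
    visit_ages.update({int(k): int(v) for k, v in
                       dict(config.get("visit_age_days", {})).items()})

    def mk(vaccine, dose_number, visit, *, min_age=None, max_age_days=max_age,
           interval_days=interval):
        age = visit_ages[visit]
        return ScheduleDose(
            vaccine=vaccine, dose_number=dose_number, visit_number=visit,
            scheduled_age_days=age,
            min_age_days=age if min_age is None else min_age,
            max_age_days=max_age_days, min_interval_days=interval_days)

    doses = (
        mk("BCG", 0, 1, min_age=0, max_age_days=bcg_max, interval_days=0),
        mk("OPV", 0, 1, min_age=0, max_age_days=opv0_window, interval_days=0),
        mk("OPV", 1, 2),
        mk("Penta", 1, 2, interval_days=0),
        mk("PCV", 1, 2, interval_days=0),
        mk("Rota", 1, 2, max_age_days=rota_max, interval_days=0),
        mk("OPV", 2, 3),
        mk("Penta", 2, 3),
        mk("PCV", 2, 3),
        mk("Rota", 2, 3, max_age_days=rota_max),
        mk("OPV", 3, 4),
        mk("Penta", 3, 4),
        mk("PCV", 3, 4),
        mk("MCV", 1, 5, interval_days=0),
        mk("MCV", 2, 6),
    )
    return Schedule(doses=doses, opv0_window_days=opv0_window)


def scheduled_date(schedule: Schedule, birth_date: dt.date,
                   vaccine: str, dose_number: int) -> dt.date:
    """Calendar date on which a dose is scheduled: birth + scheduled age."""
    d = schedule.dose(vaccine, dose_number)
    return birth_date + dt.timedelta(days=d.scheduled_age_days)


def is_timely(schedule: Schedule, birth_date: dt.date, date_given: dt.date,
              vaccine: str, dose_number: int,
              window_days: int = TIMELINESS_WINDOW_DAYS) -> bool:
    """True iff the dose was given within the grace window of its scheduled
    date and not before its minimum age.

    The window is one-sided late: on-or-before ``scheduled + window_days``
    is timely (a child becomes a defaulter only after the window).
    """
    d = schedule.dose(vaccine, dose_number)
    sched = birth_date + dt.timedelta(days=d.scheduled_age_days)
    if date_given < birth_date + dt.timedelta(days=d.min_age_days):
        return False
    return date_given <= sched + dt.timedelta(days=window_days)
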