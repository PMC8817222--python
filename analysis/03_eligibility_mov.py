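#!/usr/bin/env python
"""Missed opportunities for vaccination.

Assesses every immunization-system contact with the schedule-driven
eligibility engine, then tabulates visits with an MOV by stratum, the
distribution of recorded reasons, and the per-child MOV burden.
"""

import pandas as pd

from _common import emit, load_clean, default_schedule
from eirkit import eligibility as el
from eirkit import movement as mv


def main() -> None:
    _, live, _ = load_clean()
    schedule = default_schedule()
    assessments, missed = el.assess_bundle(live, schedule)

    fac = live.facilities.copy()
    fac["urbanicity"] = mv.derive_urbanicity(fac)
    cov = live.visits.merge(
        live.patients[["patient_id", "sex", "assigned_facility_id"]],
        on="patient_id")
    cov = cov.merge(
        fac.rename(columns={"facility_id": "assigned_facility_id"})[
            ["assigned_facility_id", "urbanicity", "ftype"]],
        on="assigned_facility_id", how="left")

    table = el.mov_tables(assessments, cov[["visit_id", "sex", "urbanicity",
                                            "ftype"]],
                          ["sex", "urbanicity", "ftype"])
    emit(table, "mov_by_stratum")
    emit(el.mov_reason_table(missed), "mov_reasons")
    per_child, agg = el.per_child_mov_summary(assessments)
    emit(pd.DataFrame([agg]), "mov_per_child_summary")

    overall = table[table["variable"] == "overall"].iloc[0]
    print(f"{overall['n_visits']} visits assessed; "
          f"{overall['pct_mov_any']:.2f}% had a missed opportunity")
    print(f"mean MOVs per child: {agg['mean_movs']:.2f} "
          f"(SD {agg['sd_movs']:.2f}); "
          f"{agg['pct_ge1']:.2f}% of children had at least one")


if __name__ == "__main__":
    main()
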