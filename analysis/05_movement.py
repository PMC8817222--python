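#!/usr/bin/env python
"""Population movement: care-seeking away from the assigned facility.

Classifies every visit into the five distance/administrative bands and
summarizes nonassigned attendance by patient and facility covariates.
"""

from _common import emit, load_clean
from eirkit import movement as mv


def main() -> None:
    _, live, _ = load_clean()
    records = mv.classify_visits(live.visits, live.patients, live.facilities)

    fac = live.facilities.copy()
    fac["urbanicity"] = mv.derive_urbanicity(fac)
    fac = fac.merge(mv.facility_density(fac), on="facility_id")
    cov = live.visits.merge(
        live.patients[["patient_id", "sex", "assigned_facility_id"]],
        on="patient_id")
    cov = cov.merge(
        fac.rename(columns={"facility_id": "assigned_facility_id",
                            "region": "assigned_region"})[
            ["assigned_facility_id", "assigned_region", "urbanicity",
             "ftype", "ownership", "density_band"]],
        on="assigned_facility_id", how="left")

    by_stratum, band_comp = mv.movement_tables(
        records, cov[["visit_id", "sex", "assigned_region", "urbanicity",
                      "ftype", "ownership", "density_band"]],
        ["sex", "urbanicity", "ftype", "ownership", "density_band"])
    emit(by_stratum, "movement_by_stratum")
    emit(band_comp, "movement_bands_by_region")
    emit(mv.assigned_attendance_by_facility(records), "assigned_attendance")

    overall = by_stratum.iloc[0]
    print(f"{overall['n_visits']} visits: {overall['pct_nonassigned']:.2f}% "
          f"at a nonassigned facility")
    bands = records["band"].value_counts()
    for band in mv.BANDS[1:]:
        print(f"  {band:<28} {bands.get(band, 0):>6}")


if __name__ == "__main__":
    main()
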