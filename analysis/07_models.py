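#!/usr/bin/env python
"""Mixed-effects regression for the nonassigned-visit outcome.

Fits unadjusted and adjusted mixed-effects logistic models with nested
region/district/facility random intercepts and writes the formatted
OR/aOR table.
"""

from _common import emit, load_clean
from eirkit import models as md
from eirkit import movement as mv


def main() -> None:
    _, live, _ = load_clean()
    records = mv.classify_visits(live.visits, live.patients, live.facilities)
    fac = live.facilities.copy()
    fac["urbanicity"] = mv.derive_urbanicity(fac)
    table = records.merge(
        fac.rename(columns={"facility_id": "assigned_facility_id"})[
            ["assigned_facility_id", "region", "district", "urbanicity",
             "ftype", "ownership"]],
        on="assigned_facility_id", how="left")
    table = table.merge(live.patients[["patient_id", "sex"]], on="patient_id")
    table = table.rename(columns={"assigned_facility_id": "facility_id"})
    table["outcome"] = table["nonassigned"].astype(int)

    covs = [md.Covariate("urbanicity", "categorical", reference="rural"),
            md.Covariate("sex", "categorical", reference="female"),
            md.Covariate("ftype", "categorical", reference="dispensary"),
            md.Covariate("ownership", "categorical", reference="private")]
    unadj_spec = md.ModelSpec(outcome="outcome", fixed_effects=[covs[0]],
                              adjusted=False)
    adj_spec = md.ModelSpec(outcome="outcome", fixed_effects=covs)

    results = {}
    for label, spec in (("unadjusted", unadj_spec), ("adjusted", adj_spec)):
        res = md.fit_mixed_logit(md.build_design(table, spec), spec)
        results[label] = res
        print(f"{label}: method={res.method}, nesting={res.nesting_used}, "
              f"cluster SDs={ {k: round(v, 3) for k, v in res.vc_sd.items()} }")
        if res.fallback:
            print(f"  note: {res.fallback}")
    emit(md.result_table(results), "movement_model_or_table")


if __name__ == "__main__":
    main()
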