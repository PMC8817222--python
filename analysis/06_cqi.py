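#!/usr/bin/env python
"""Continuous quality improvement: how concentrated are the issues?

Aggregates nonassigned visits (by assigned facility), MOV visits (by
visited facility) and dropped-out children (by assigned facility), then
computes the share of each issue held by the top 10/25/50/75% of
facilities, plus per-facility stockout indicators.
"""

from _common import CENSUS, emit, load_clean, default_schedule
import pandas as pd
from eirkit import continuum as ct
from eirkit import cqi
from eirkit import eligibility as el
from eirkit import movement as mv


def main() -> None:
    bundle, live, _ = load_clean()
    cont = load_clean(include_back_entered=True)[1]
    schedule = default_schedule()

    records = mv.classify_visits(live.visits, live.patients, live.facilities)
    assessments, _ = el.assess_bundle(live, schedule)
    cards = ct.build_cards(cont, schedule, CENSUS)

    ledger = cqi.build_issue_ledger(records, assessments, cards)
    all_fac = sorted(bundle.facilities["facility_id"])
    curves = []
    for issue in cqi.ISSUE_TYPES:
        c = cqi.concentration_curve(ledger, issue, all_facility_ids=all_fac)
        c["issue_type"] = issue
        curves.append(c)
    curves = pd.concat(curves, ignore_index=True)
    emit(curves, "cqi_concentration")
    emit(cqi.stockout_summary(live.stock), "stockout_by_facility")

    print(f"{len(all_fac)} facilities")
    for issue in cqi.ISSUE_TYPES:
        top = curves[(curves["issue_type"] == issue)
                     & (curves["quantile"] == 0.10)]
        if len(top):
            print(f"  top 10% of facilities hold "
                  f"{top.iloc[0]['pct_issues']:.2f}% of {issue}")


if __name__ == "__main__":
    main()
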