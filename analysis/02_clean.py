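#!/usr/bin/env python
"""Apply the registry cleaning rules and report what they removed.

Campaign dummy IDs (>3 administered records of one dose slot), duplicate
dose records (earliest kept), and — for the live-entry analysis set —
back-entered doses.  Prints before/after row counts per table.
"""

from _common import load_bundle, emit
import pandas as pd
from eirkit.data_model import clean_bundle


def main() -> None:
    bundle = load_bundle()
    live, log = clean_bundle(bundle, include_back_entered=False)
    cont, _ = clean_bundle(bundle, include_back_entered=True)

    print(f"campaign dummy IDs excluded: {len(log.excluded_campaign_ids)}")
    rows = []
    for name in log.counts_before:
        rows.append({"table": name, "rows_raw": log.counts_before[name],
                     "rows_live_clean": log.counts_after[name],
                     "rows_continuum_clean": len(cont.table(name))})
        print(f"  {name:<10} {log.counts_before[name]:>7} -> "
              f"{log.counts_after[name]:>7} (live) / "
              f"{len(cont.table(name)):>7} (continuum)")
    emit(pd.DataFrame(rows), "cleaning_counts")


if __name__ == "__main__":
    main()
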