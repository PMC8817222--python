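"""Continuous quality improvement: facility concentration of issues and
stockout indicators.

The concentration curve answers "what share of quality issues (missed
opportunities, nonassigned visits, dropped-out children) is accounted
for by the top q fraction of facilities?"  Facilities are ranked by
descending issue count (ties broken by facility ID for determinism) over
the full facility universe, so facilities with zero issues pad the tail
and the curve can reach 100% before q = 1.

Attribution rules: missed-opportunity visits are attributed to the
facility where the visit happened; nonassigned visits and dropped-out
children are attributed to the child's assigned facility.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

ISSUE_TYPES = ("nonassigned_visits", "mov_visits", "dropout_children")

STOCKOUT_BANDS = ("<10%", "10%-19%", "20%-29%", ">=30%")

PRIMARY_VACCINES = ("BCG", "OPV", "PCV", "Penta", "Rota", "MCV")


def build_issue_ledger(movement_records: Optional[pd.DataFrame],
                       assessments: Optional[pd.DataFrame],
                       cards: Optional[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-facility issue counts.

    * ``nonassigned_visits`` — visits away from home, per assigned facility;
    * ``mov_visits`` — visits with any MOV, per visited facility;
    * ``dropout_children`` — children with overall dropout, per assigned
      facility.
    """
    frames = []
    if movement_records is not None:
        na = movement_records[movement_records["nonassigned"]]
        g = na.groupby("assigned_facility_id").size()
        frames.append(pd.DataFrame({
            "facility_id": g.index, "issue_type": "nonassigned_visits",
            "count": g.values, "attribution": "assigned_facility"}))
    if assessments is not None:
        mov = assessments[assessments["mov_any"]]
        g = mov.groupby("facility_id").size()
        frames.append(pd.DataFrame({
            "facility_id": g.index, "issue_type": "mov_visits",
            "count": g.values, "attribution": "visited_facility"}))
    if cards is not None:
        dro = cards[cards["dropout_overall"]]
        g = dro.groupby("assigned_facility_id").size()
        frames.append(pd.DataFrame({
            "facility_id": g.index, "issue_type": "dropout_children",
            "count": g.values, "attribution": "assigned_facility"}))
    if not frames:
        return pd.DataFrame(columns=["facility_id", "issue_type", "count",
                                     "attribution"])
    return pd.concat(frames, ignore_index=True)


def concentration_curve(ledger: pd.DataFrame, issue_type: str,
                        quantiles: Sequence[float] = (0.10, 0.25, 0.50, 0.75),
                        all_facility_ids: Optional[Sequence[str]] = None,
                        head_counts: Optional[Sequence[int]] = None
                        ) -> pd.DataFrame:
    """Share of issues accounted for by the top-q facilities.

    Facilities are ranked by descending count then facility ID.  The
    facility universe defaults to facilities appearing in the ledger;
    pass ``all_facility_ids`` to include zero-issue facilities in the
    denominator of q.  The head size is ceil(q * n facilities) unless
    explicit ``head_counts`` are given (one per quantile) — the
    printed-head-count convention used by some reports.

    Returns an empty frame when total issues are zero (curve undefined).
    """
    sub = ledger[ledger["issue_type"] == issue_type]
    counts = sub.groupby("facility_id")["count"].sum()
    if all_facility_ids is not None:
        counts = counts.reindex(list(all_facility_ids), fill_value=0)
    counts = counts.reset_index().sort_values(
        ["count", "facility_id"], ascending=[False, True], kind="stable")
    total = int(counts["count"].sum())
    if total == 0:
        return pd.DataFrame(columns=["quantile", "n_head", "n_issues",
                                     "pct_issues"])
    n_fac = len(counts)
    cum = counts["count"].cumsum().to_numpy()
    rows = []
    for i, q in enumerate(quantiles):
        head = (int(head_counts[i]) if head_counts is not None
                else math.ceil(q * n_fac))
        head = min(max(head, 0), n_fac)
        n_issues = int(cum[head - 1]) if head else 0
        rows.append({"quantile": q, "n_head": head, "n_issues": n_issues,
                     "pct_issues": 100 * n_issues / total})
    return pd.DataFrame(rows)


def stockout_band(pct) -> Optional[str]:
    """Composite stockout reporting band; edges half-open at the printed
    boundaries (10.0% falls in '10%-19%')."""
    if pd.isna(pct):
        return None
    if pct < 10:
        return "<10%"
    if pct < 20:
        return "10%-19%"
    if pct < 30:
        return "20%-29%"
    return ">=30%"


def stockout_summary(stock: pd.DataFrame,
                     vaccines: Sequence[str] = PRIMARY_VACCINES
                     ) -> pd.DataFrame:
    """Per-facility stockout summary over the primary vaccines.

    A stockout day is a facility-vaccine-day with zero recorded balance.
    The composite is the percentage of facility-vaccine-days with data
    that were stockout days; facilities with no stock data get a null
    composite (excluded from stockout strata).
    """
    sub = stock[stock["vaccine"].isin(vaccines)]
    per_vac = (sub.assign(zero=sub["balance"] == 0)
               .groupby(["facility_id", "vaccine"])
               .agg(n_days=("balance", "size"), n_zero=("zero", "sum")))
    wide_zero = per_vac["n_zero"].unstack(fill_value=0)
    totals = per_vac.groupby("facility_id").agg(
        n_days_total=("n_days", "sum"), n_zero_total=("n_zero", "sum"))
    out = totals.reset_index()
    out["composite_pct"] = 100 * out["n_zero_total"] / out["n_days_total"]
    out["composite_band"] = out["composite_pct"].map(stockout_band)
    for v in vaccines:
        out[f"n_zero_{v}"] = out["facility_id"].map(
            wide_zero[v] if v in wide_zero.columns else pd.Series(dtype=int)
        ).fillna(0).astype(int)
    return out
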