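"""Output-table assembly and the end-to-end pipeline.

All percentages in emitted tables go through :func:`pct`, a single
shared rounding rule (round half up at the requested precision, the
convention used in printed report tables), and every table carries raw
counts alongside percentages so outputs are auditable.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import continuum, cqi, data_model, eligibility, movement
from .schedule import Schedule, default_schedule
from .synthetic_data import SimConfig, simulate_registry

logger = logging.getLogger("eirkit")


def pct(numerator: Union[int, float], denominator: Union[int, float],
        decimals: int = 2) -> float:
    """Percentage with round-half-up at ``decimals`` places.

    Raises ZeroDivisionError for a zero denominator (an undefined cell
    must be handled explicitly by the caller, never rendered as 0).
    """
    if denominator == 0:
        raise ZeroDivisionError("undefined percentage: zero denominator")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def pct_str(numerator, denominator, decimals: int = 2) -> str:
    try:
        return f"{pct(numerator, denominator, decimals):.{decimals}f}"
    except ZeroDivisionError:
        return "undefined"


@dataclass
class AnalysisRun:
    """Record of one pipeline execution: config, outputs, cleaning log."""

    config: dict
    out_dir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    cleaning: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "config": self.config,
            "tables": {k: str(v) for k, v in self.tables.items()},
            "cleaning": self.cleaning,
            "input_hashes": self.input_hashes,
        }


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False).encode("utf-8")).hexdigest()[:16]


def run_all(bundle_or_simconfig, analysis_config: Optional[dict] = None,
            out_dir: Union[str, Path] = "results",
            schedule: Optional[Schedule] = None) -> AnalysisRun:
    """Execute the full pipeline and write the report-shaped CSVs.

    Stages: clean -> visit assessment (MOV) -> continuum -> movement ->
    CQI, each writing its tables under ``out_dir``.  Accepts either a
    validated :class:`RegistryBundle` or a :class:`SimConfig` (in which
    case the registry is simulated first).  Any stage failure aborts
    with the stage named.
    """
    cfg = dict(analysis_config or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schedule = schedule or default_schedule()

    if isinstance(bundle_or_simconfig, SimConfig):
        sim_cfg = bundle_or_simconfig
        bundle, _ = simulate_registry(sim_cfg, schedule)
        config_snapshot = {"sim": dataclasses.asdict(sim_cfg)}
    else:
        bundle = bundle_or_simconfig
        config_snapshot = {"sim": None}
    config_snapshot["analysis"] = {
        k: (str(v) if isinstance(v, (dt.date, Path)) else v)
        for k, v in cfg.items()}

    census = pd.Timestamp(cfg.get("census_date", "2019-12-31"))
    run = AnalysisRun(config=config_snapshot, out_dir=out_dir)
    run.input_hashes = {name: _hash_frame(bundle.table(name))
                        for name in data_model.TABLE_NAMES}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        run.tables[name] = path
        logger.info("stage output %s: %d rows", name, len(df))

    stage = "clean"
    try:
        live, log_live = data_model.clean_bundle(
            bundle, min_region_visits=cfg.get("min_region_visits", 0),
            cutoff_date=cfg.get("cutoff_date", census),
            include_back_entered=False)
        cont, _ = data_model.clean_bundle(
            bundle, min_region_visits=cfg.get("min_region_visits", 0),
            cutoff_date=cfg.get("cutoff_date", census),
            include_back_entered=True)
        run.cleaning = {
            "excluded_campaign_ids": sorted(log_live.excluded_campaign_ids),
            "dropped_regions": sorted(log_live.dropped_regions),
            "counts_before": log_live.counts_before,
            "counts_after": log_live.counts_after,
        }

        stage = "covariates"
        fac = live.facilities.copy()
        fac["urbanicity"] = movement.derive_urbanicity(fac)
        dens = movement.facility_density(fac)
        fac = fac.merge(dens, on="facility_id")
        visit_cov = live.visits.merge(
            live.patients[["patient_id", "sex", "birth_date",
                           "assigned_facility_id"]], on="patient_id")
        assigned_attrs = fac.rename(columns={
            "facility_id": "assigned_facility_id",
            "region": "assigned_region", "ftype": "assigned_ftype",
            "ownership": "assigned_ownership",
            "urbanicity": "assigned_urbanicity",
            "density_band": "assigned_density_band",
            "golive_date": "assigned_golive"})
        visit_cov = visit_cov.merge(
            assigned_attrs[["assigned_facility_id", "assigned_region",
                            "assigned_ftype", "assigned_ownership",
                            "assigned_urbanicity", "assigned_density_band",
                            "assigned_golive"]],
            on="assigned_facility_id", how="left")
        visit_cov["eir_duration_band"] = (
            (visit_cov["visit_date"] - visit_cov["assigned_golive"])
            .dt.days.map(movement.eir_duration_band))

        stage = "mov"
        assessments, missed = eligibility.assess_bundle(live, schedule)
        visited_attrs = fac.rename(columns={
            "urbanicity": "visited_urbanicity", "ftype": "visited_ftype"})
        mov_cov = (visit_cov[["visit_id", "sex", "assigned_urbanicity",
                              "assigned_ftype", "eir_duration_band"]])
        emit("mov_by_stratum", eligibility.mov_tables(
            assessments, mov_cov,
            ["sex", "assigned_urbanicity", "assigned_ftype",
             "eir_duration_band"]))
        emit("mov_reasons", eligibility.mov_reason_table(missed))
        per_child, agg = eligibility.per_child_mov_summary(assessments)
        emit("mov_per_child", pd.DataFrame([agg]))

        stage = "continuum"
        cards = continuum.build_cards(
            cont, schedule, census,
            age_min_months=cfg.get("age_min_months", 12),
            age_max_months=cfg.get("age_max_months", 47))
        cards = cards.merge(
            assigned_attrs[["assigned_facility_id", "assigned_urbanicity",
                            "assigned_ftype", "assigned_ownership"]],
            on="assigned_facility_id", how="left")
        emit("coverage_timeliness",
             continuum.coverage_timeliness(cards, schedule))
        emit("visit_touchpoints", continuum.visit_touchpoints(cards, schedule))
        emit("dropout_by_stratum", continuum.dropout_table(
            cards, ["sex", "assigned_urbanicity", "assigned_ftype",
                    "assigned_ownership"]))
        emit("typologies", continuum.typology_table(
            cards, top_k=cfg.get("typology_top_k", 10)))

        stage = "movement"
        records = movement.classify_visits(live.visits, live.patients,
                                           live.facilities)
        by_stratum, band_comp = movement.movement_tables(
            records,
            visit_cov[["visit_id", "sex", "assigned_region",
                       "assigned_urbanicity", "assigned_ftype",
                       "assigned_ownership", "assigned_density_band",
                       "eir_duration_band"]],
            ["sex", "assigned_urbanicity", "assigned_ftype",
             "assigned_ownership", "assigned_density_band",
             "eir_duration_band"])
        emit("movement_by_stratum", by_stratum)
        emit("movement_bands_by_region", band_comp)
        emit("assigned_attendance",
             movement.assigned_attendance_by_facility(records))

        stage = "cqi"
        ledger = cqi.build_issue_ledger(records, assessments, cards)
        all_fac = sorted(bundle.facilities["facility_id"])
        curves = []
        for issue in cqi.ISSUE_TYPES:
            c = cqi.concentration_curve(ledger, issue,
                                        all_facility_ids=all_fac)
            c["issue_type"] = issue
            curves.append(c)
        emit("cqi_concentration", pd.concat(curves, ignore_index=True))
        emit("stockout_summary", cqi.stockout_summary(live.stock))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(run.manifest(), fh, indent=2, default=str)
    return run
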