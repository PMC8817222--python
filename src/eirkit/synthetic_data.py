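"""Synthetic immunization-registry generator.

Emulates the statistical structure of a national electronic
immunization registry extract: facilities nested in districts nested in
regions, children assigned to a home facility, visit-by-visit dose
acquisition through the first-year schedule, per-dose withholding
(missed opportunities), care-seeking at nonassigned facilities with
distance decay, a facility stock ledger with stockout days, and
back-entered records.

Dose acquisition is simulated as visit attendance x per-dose
withholding, so the missed-opportunity rate and the dropout rate are
separately controllable: attendance follows a stopping process with a
continuation probability per scheduled visit (a child who misses a
visit never returns), and at every attended visit each dose the child
is eligible for — computed with the same eligibility rules the analyses
use — is withheld with the configured probability.  Because attendance
is a stopping process, the dropout rates implied by the continuation
probabilities have closed forms (recorded in the ground truth) when
withholding is off.

Everything is driven by one integer seed; the same seed reproduces the
registry byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import eligibility
from .data_model import RegistryBundle, validate_bundle
from .schedule import Schedule, default_schedule

VACCINES = ("BCG", "OPV", "Penta", "PCV", "Rota", "MCV")


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _sigmoid(x: float) -> float:
    return 1 / (1 + math.exp(-x))


@dataclass
class SimConfig:
    """Generator configuration.  Defaults emulate the study conditions:
    ~5.5% of visits at nonassigned facilities, roughly a quarter of
    visits with a missed opportunity, visit-touchpoint continuation
    declining from ~0.96 at birth to ~0.71 at the measles visit, and a
    reason mix dominated by stockouts."""

    seed: int = 0
    # spatial/administrative structure
    n_regions: int = 4
    districts_per_region: int = 3
    facilities_per_district: int = 4
    region_spacing_deg: float = 1.5
    district_spread_deg: float = 0.35
    facility_spread_deg: float = 0.03
    # facility attributes
    ftype_probs: tuple[float, float, float] = (0.80, 0.15, 0.05)
    ownership_public_prob: float = 0.80
    density_logmean: float = 5.0
    density_logsd: float = 1.4
    # cohort
    n_children: int = 2000
    birth_start: dt.date = dt.date(2016, 6, 1)
    birth_end: dt.date = dt.date(2019, 6, 30)
    census_date: dt.date = dt.date(2019, 12, 31)
    study_start: dt.date = dt.date(2017, 1, 1)
    golive_start: dt.date = dt.date(2017, 1, 1)
    golive_end: dt.date = dt.date(2019, 6, 30)
    # attendance: continuation probability per scheduled visit 1..6
    visit_continuation: tuple[float, ...] = (0.963, 0.967, 0.869, 0.834,
                                             0.714, 0.55)
    visit_delay_mean_days: float = 4.0
    # missed opportunities
    mov_mode: str = "per_dose"          # or "per_visit"
    mov_per_dose_prob: float = 0.08
    mov_visit_prob: float = 0.25
    mov_reason_probs: dict = field(default_factory=lambda: {
        "stockout": 0.525, "contraindication": 0.007, "late": 0.009,
        "refusal": 0.0005, "expired_stock": 0.0005, "none": 0.458})
    mov_re_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # movement
    movement_prob: float = 0.055
    movement_decay_km: float = 5.0
    movement_re_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    movement_urban_logodds: float = 0.0
    # stock ledger
    stockout_day_rate: float = 0.10
    stock_days_per_facility_vaccine: int = 120
    # data-entry behaviour
    back_entry_prob: float = 0.03

    def validate(self) -> None:
        if self.n_regions * self.districts_per_region \
                * self.facilities_per_district < 1:
            raise ValueError("at least one facility required")
        probs = [self.mov_per_dose_prob, self.mov_visit_prob,
                 self.movement_prob, self.stockout_day_rate,
                 self.back_entry_prob, *self.visit_continuation]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.mov_mode not in ("per_dose", "per_visit"):
            raise ValueError(f"unknown mov_mode {self.mov_mode!r}")


@dataclass
class GroundTruth:
    """Latent states and model-implied rates for estimator validation."""

    config: SimConfig
    expected_nonassigned_rate: float = np.nan
    expected_mov_any_rate: float = np.nan
    expected_mov_per_dose_rate: float = np.nan
    #: closed-form dropout probabilities implied by the continuation
    #: probabilities (valid in the no-withholding limit)
    expected_dropout: dict = field(default_factory=dict)
    last_visit_attended: dict = field(default_factory=dict)
    movement_re: dict = field(default_factory=dict)
    # injected edge cases (filled by inject_edge_cases)
    campaign_ids: set = field(default_factory=set)
    duplicate_records: list = field(default_factory=list)
    back_entered_only_ids: set = field(default_factory=set)
    no_geocode_facilities: set = field(default_factory=set)
    no_stock_facilities: set = field(default_factory=set)


def _expected_dropout(c: tuple[float, ...]) -> dict:
    """Dropout probabilities implied by the attendance stopping process
    (conditioned on the starting dose, as the analysis denominators are)."""
    _, c2, c3, c4, c5 = c[:5]
    return {
        "dropout_penta": 1 - c3 * c4,
        "dropout_pcv": 1 - c3 * c4,
        "dropout_rota": 1 - c3,
        "dropout_opv": 1 - c2 * c3 * c4,
        "dropout_birth_to_first": 1 - c2,
        "dropout_overall": 1 - c2 * c3 * c4 * c5,
    }


def _make_facilities(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    study_days = (cfg.golive_end - cfg.golive_start).days
    fid = 0
    for r in range(cfg.n_regions):
        region = f"R{r + 1:02d}"
        base_lat = -8.0 + cfg.region_spacing_deg * (r // 3)
        base_lon = 32.0 + cfg.region_spacing_deg * (r % 3)
        for d in range(cfg.districts_per_region):
            district = f"{region}D{d + 1:02d}"
            dlat = base_lat + rng.normal(0, cfg.district_spread_deg)
            dlon = base_lon + rng.normal(0, cfg.district_spread_deg)
            for _ in range(cfg.facilities_per_district):
                fid += 1
                ftype = ("dispensary", "health_center", "hospital")[
                    rng.choice(3, p=cfg.ftype_probs)]
                rows.append({
                    "facility_id": f"F{fid:04d}",
                    "region": region, "district": district,
                    "lat": dlat + rng.normal(0, cfg.facility_spread_deg),
                    "lon": dlon + rng.normal(0, cfg.facility_spread_deg),
                    "ftype": ftype,
                    "ownership": ("public"
                                  if rng.random() < cfg.ownership_public_prob
                                  else "private"),
                    "ward_density": float(np.round(
                        rng.lognormal(cfg.density_logmean, cfg.density_logsd),
                        1)),
                    "golive_date": pd.Timestamp(cfg.golive_start)
                    + pd.Timedelta(days=int(rng.integers(0, study_days + 1))),
                })
    return pd.DataFrame(rows)


def _cluster_effects(facilities: pd.DataFrame, sds: tuple[float, float, float],
                     rng: np.random.Generator) -> np.ndarray:
    """Per-facility random intercept: region + district + facility terms."""
    regions = sorted(facilities["region"].unique())
    districts = sorted(facilities["district"].unique())
    re_r = dict(zip(regions, rng.normal(0, sds[0], len(regions))))
    re_d = dict(zip(districts, rng.normal(0, sds[1], len(districts))))
    re_f = rng.normal(0, sds[2], len(facilities))
    return (facilities["region"].map(re_r).to_numpy()
            + facilities["district"].map(re_d).to_numpy() + re_f)


def simulate_registry(config: SimConfig,
                      schedule: Optional[Schedule] = None
                      ) -> tuple[RegistryBundle, GroundTruth]:
    """Simulate a registry bundle plus its ground truth.

    The output conforms to the registry schema and passes validation.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    schedule = schedule or default_schedule()
    truth = GroundTruth(config=dataclasses.replace(cfg),
                        expected_mov_per_dose_rate=cfg.mov_per_dose_prob,
                        expected_dropout=_expected_dropout(
                            cfg.visit_continuation))

    facilities = _make_facilities(cfg, rng)
    n_fac = len(facilities)
    fac_id_arr = facilities["facility_id"].to_numpy()
    move_re = _cluster_effects(facilities, cfg.movement_re_sd, rng)
    mov_re = _cluster_effects(facilities, cfg.mov_re_sd, rng)
    truth.movement_re = dict(zip(facilities["facility_id"], move_re))
    urban = (facilities["ward_density"] >= 500).to_numpy()

    # pre-compute movement destination kernels (distance-decay choice
    # among the other facilities)
    from .movement import haversine_km
    lat = facilities["lat"].to_numpy()
    lon = facilities["lon"].to_numpy()
    dmat = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    kernels = []
    for i in range(n_fac):
        w = np.exp(-dmat[i] / cfg.movement_decay_km)
        w[i] = 0.0
        s = w.sum()
        kernels.append(w / s if s > 0 else None)

    visit_ages = {k: schedule.doses_for_visit(k)[0].scheduled_age_days
                  for k in range(1, 7)}
    census = pd.Timestamp(cfg.census_date)
    birth_span = (cfg.birth_end - cfg.birth_start).days
    move_base = _logit(cfg.movement_prob) if 0 < cfg.movement_prob < 1 else None
    movd_base = (_logit(cfg.mov_per_dose_prob)
                 if 0 < cfg.mov_per_dose_prob < 1 else None)
    reasons = sorted(cfg.mov_reason_probs)
    reason_p = np.array([cfg.mov_reason_probs[r] for r in reasons])
    reason_p = reason_p / reason_p.sum()

    patients_rows, visit_rows, dose_rows = [], [], []
    forced_stockouts: set[tuple[str, str, pd.Timestamp]] = set()
    sum_p_move = 0.0
    sum_p_any = 0.0
    n_live_visits = 0
    visit_counter = 0

    for i in range(cfg.n_children):
        pid = f"P{i + 1:06d}"
        birth = pd.Timestamp(cfg.birth_start) + pd.Timedelta(
            days=int(rng.integers(0, birth_span + 1)))
        fac_idx = int(rng.integers(0, n_fac))
        sex = "female" if rng.random() < 0.5 else "male"
        patients_rows.append({
            "patient_id": pid, "sex": sex, "birth_date": birth,
            "assigned_facility_id": fac_id_arr[fac_idx],
            "registration_date": birth})
        back_child = rng.random() < cfg.back_entry_prob

        history: dict[tuple[str, int], pd.Timestamp] = {}
        cum_delay = 0
        last_visit = 0
        for k in range(1, 7):
            if rng.random() >= cfg.visit_continuation[k - 1]:
                break
            if k > 1:
                cum_delay += int(round(rng.exponential(
                    cfg.visit_delay_mean_days)))
            visit_date = birth + pd.Timedelta(days=visit_ages[k] + cum_delay)
            if visit_date > census:
                break
            last_visit = k

            # care-seeking: stay home or relocate with distance decay
            vis_idx = fac_idx
            if move_base is not None and kernels[fac_idx] is not None:
                p_move = _sigmoid(move_base + move_re[fac_idx]
                                  + (cfg.movement_urban_logodds
                                     if urban[fac_idx] else 0.0))
                if rng.random() < p_move:
                    vis_idx = int(rng.choice(n_fac, p=kernels[fac_idx]))
            else:
                p_move = 0.0

            back_visit = back_child and k == 1
            entry_mode = "back_entered" if back_visit else "live"
            visit_id = ""
            if not back_visit:
                visit_counter += 1
                visit_id = f"V{visit_counter:07d}"
                visit_rows.append({
                    "visit_id": visit_id, "patient_id": pid,
                    "facility_id": fac_id_arr[vis_idx],
                    "visit_date": visit_date})
                sum_p_move += p_move
                n_live_visits += 1

            elig = sorted(eligibility.eligible_at(
                schedule, history, birth, visit_date))
            withheld: set = set()
            if cfg.mov_mode == "per_dose":
                p_dose = (cfg.mov_per_dose_prob if movd_base is None
                          else _sigmoid(movd_base + mov_re[vis_idx]))
                for key in elig:
                    if rng.random() < p_dose:
                        withheld.add(key)
                p_any = 1 - (1 - p_dose) ** len(elig)
            else:
                p_any = cfg.mov_visit_prob if elig else 0.0
                if elig and rng.random() < cfg.mov_visit_prob:
                    withheld.add(elig[int(rng.integers(0, len(elig)))])
            if not back_visit:
                sum_p_any += p_any

            for key in elig:
                vac, num = key
                if key in withheld:
                    reason = reasons[int(rng.choice(len(reasons), p=reason_p))]
                    if reason == "none":
                        continue  # silent miss: no record at all
                    dose_rows.append({
                        "patient_id": pid, "visit_id": visit_id,
                        "vaccine": vac, "dose_number": num,
                        "date_given": visit_date, "entry_mode": entry_mode,
                        "missed_reason": reason})
                    if reason == "stockout":
                        forced_stockouts.add(
                            (fac_id_arr[vis_idx], vac,
                             visit_date))
                else:
                    dose_rows.append({
                        "patient_id": pid, "visit_id": visit_id,
                        "vaccine": vac, "dose_number": num,
                        "date_given": visit_date, "entry_mode": entry_mode,
                        "missed_reason": "none"})
                    history[key] = visit_date
        truth.last_visit_attended[pid] = last_visit

    truth.expected_nonassigned_rate = (sum_p_move / n_live_visits
                                       if n_live_visits else np.nan)
    truth.expected_mov_any_rate = (sum_p_any / n_live_visits
                                   if n_live_visits else np.nan)

    stock_rows = []
    span = (cfg.census_date - cfg.study_start).days
    for fac_id in facilities["facility_id"]:
        for vac in VACCINES:
            n_days = min(cfg.stock_days_per_facility_vaccine, span + 1)
            offsets = np.sort(rng.choice(span + 1, size=n_days, replace=False))
            zeros = rng.random(n_days) < cfg.stockout_day_rate
            for off, z in zip(offsets, zeros):
                date = pd.Timestamp(cfg.study_start) + pd.Timedelta(
                    days=int(off))
                balance = 0 if z else int(5 + rng.poisson(20))
                stock_rows.append({"facility_id": fac_id, "vaccine": vac,
                                   "date": date, "balance": balance})
    stock = pd.DataFrame(stock_rows)
    # keep the stock ledger consistent with stockout-reason misses
    if forced_stockouts:
        key = pd.MultiIndex.from_frame(stock[["facility_id", "vaccine", "date"]])
        forced = pd.MultiIndex.from_tuples(sorted(forced_stockouts),
                                           names=["facility_id", "vaccine",
                                                  "date"])
        stock.loc[key.isin(forced), "balance"] = 0
        missing = forced[~forced.isin(key)]
        if len(missing):
            extra = pd.DataFrame(
                [{"facility_id": f, "vaccine": v, "date": d, "balance": 0}
                 for f, v, d in missing])
            stock = pd.concat([stock, extra], ignore_index=True)
        stock = stock.sort_values(["facility_id", "vaccine", "date"],
                                  kind="stable").reset_index(drop=True)

    bundle = RegistryBundle(
        patients=pd.DataFrame(patients_rows),
        facilities=facilities,
        visits=pd.DataFrame(visit_rows, columns=["visit_id", "patient_id",
                                                 "facility_id", "visit_date"]),
        doses=pd.DataFrame(dose_rows, columns=["patient_id", "visit_id",
                                               "vaccine", "dose_number",
                                               "date_given", "entry_mode",
                                               "missed_reason"]),
        stock=stock)
    validate_bundle(bundle)
    return bundle, truth


@dataclass
class EdgeCaseConfig:
    """How many of each pathological record pattern to inject."""

    n_campaign_ids: int = 10
    campaign_repeats: int = 5
    n_duplicate_doses: int = 20
    n_back_entered_only: int = 10
    n_missing_geocode: int = 2
    n_missing_stock: int = 2


def inject_edge_cases(bundle: RegistryBundle, truth: GroundTruth,
                      edge: EdgeCaseConfig,
                      seed: int = 0) -> tuple[RegistryBundle, GroundTruth]:
    """Add campaign dummy IDs, duplicate dose records, back-entered-only
    patients and facilities lacking geocodes/stock, tagging each in the
    ground truth so cleaning rules can be verified exactly."""
    rng = np.random.default_rng(seed)
    out = bundle.copy()
    fac_ids = list(out.facilities["facility_id"])
    birth = pd.Timestamp("2018-01-01")

    new_patients, new_doses = [], []
    for i in range(edge.n_campaign_ids):
        pid = f"CAMP{i + 1:04d}"
        truth.campaign_ids.add(pid)
        new_patients.append({
            "patient_id": pid, "sex": "unknown", "birth_date": birth,
            "assigned_facility_id": fac_ids[int(rng.integers(0, len(fac_ids)))],
            "registration_date": birth})
        for j in range(edge.campaign_repeats):
            new_doses.append({
                "patient_id": pid, "visit_id": "", "vaccine": "OPV",
                "dose_number": 1,
                "date_given": birth + pd.Timedelta(days=42 + 7 * j),
                "entry_mode": "live", "missed_reason": "none"})

    for i in range(edge.n_back_entered_only):
        pid = f"BACK{i + 1:04d}"
        truth.back_entered_only_ids.add(pid)
        new_patients.append({
            "patient_id": pid, "sex": "unknown", "birth_date": birth,
            "assigned_facility_id": fac_ids[int(rng.integers(0, len(fac_ids)))],
            "registration_date": birth})
        for vac, num, age in (("BCG", 0, 0), ("Penta", 1, 42)):
            new_doses.append({
                "patient_id": pid, "visit_id": "", "vaccine": vac,
                "dose_number": num,
                "date_given": birth + pd.Timedelta(days=age),
                "entry_mode": "back_entered", "missed_reason": "none"})

    admin = out.doses[(out.doses["missed_reason"] == "none")
                      & (out.doses["entry_mode"] == "live")]
    n_dup = min(edge.n_duplicate_doses, len(admin))
    if n_dup:
        picks = admin.iloc[np.sort(rng.choice(len(admin), size=n_dup,
                                              replace=False))]
        for row in picks.itertuples():
            truth.duplicate_records.append(
                (row.patient_id, row.vaccine, int(row.dose_number),
                 row.date_given))
            new_doses.append({
                "patient_id": row.patient_id, "visit_id": "",
                "vaccine": row.vaccine, "dose_number": int(row.dose_number),
                "date_given": row.date_given + pd.Timedelta(days=3),
                "entry_mode": "live", "missed_reason": "none"})

    if new_patients:
        out.patients = pd.concat([out.patients, pd.DataFrame(new_patients)],
                                 ignore_index=True)
    if new_doses:
        out.doses = pd.concat([out.doses, pd.DataFrame(new_doses)],
                              ignore_index=True)

    if edge.n_missing_geocode:
        drop = fac_ids[:edge.n_missing_geocode]
        truth.no_geocode_facilities.update(drop)
        mask = out.facilities["facility_id"].isin(drop)
        out.facilities.loc[mask, ["lat", "lon"]] = np.nan
    if edge.n_missing_stock:
        drop = fac_ids[-edge.n_missing_stock:]
        truth.no_stock_facilities.update(drop)
        out.stock = out.stock[~out.stock["facility_id"].isin(drop)]
    return out, truth
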