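# eirkit

Analytics for electronic immunization registries (EIRs): a
schedule-driven dose-eligibility and missed-opportunity engine,
continuum-of-care metrics, population-movement classification, facility
quality-improvement concentration curves, and mixed-effects regression
stages — exercised end-to-end on a synthetic registry generator that
emulates a national EIR's data structure (patients, visits, dose
records, facilities, stock ledger).

It is written for immunization-program analysts and health-information
researchers who have individual-level registry extracts and want
reproducible, auditable versions of the standard EIR analyses.

## What it computes

- **Missed opportunities for vaccination (MOV).** A visit contains an
  MOV when the child was eligible for a dose but did not receive it.
  Eligibility at age *a* with dose history *H* requires
  `min_age ≤ a ≤ max_age`, the previous dose of the sequence received
  at least the minimum interval (28 d) earlier, and the dose not already
  in *H*; rotavirus doses are age-capped at one year, and OPV-1 starts
  the sequence when the OPV-0 birth-dose window (14 d) has closed.
- **Continuum of care.** Per-dose coverage and timeliness (within 7 days
  of the scheduled date), vaccine-specific and overall dropout
  (first-versus-last-dose rule, e.g. Penta-1 without Penta-3), visit
  touchpoints, and immunization typologies — the 2^14 received/not
  patterns over the 14 doses scheduled in the first year of life.
- **Population movement.** Visits to nonassigned facilities, banded as
  within 5 km / same district / same region / other region using
  great-circle distance and administrative nesting.
- **CQI concentration curves.** The share of issues (MOV visits,
  nonassigned visits, dropped-out children) held by the top 10/25/50/75%
  of facilities, plus stockout-day indicators from the stock ledger.
- **Mixed-effects logistic regression** with nested random intercepts
  for region, district and facility (fit by lme4's `glmer` through
  Rscript, with a statsmodels fallback), reported as OR (95% CI) tables.

See `docs/methods.md` for the full model description, parameter
defaults, and what the synthetic generator does and does not emulate.

## Worked example

The numbered drivers under `analysis/` run the whole study on a
simulated registry (4,000 children, 48 facilities, seed 17):

```bash
cd analysis
python 01_simulate.py && python 02_clean.py && python 03_eligibility_mov.py
python 04_continuum.py && python 05_movement.py && python 06_cqi.py
python 07_models.py
```

which prints, among other things:

```
campaign dummy IDs excluded: 10
15738 visits assessed; 23.70% had a missed opportunity
mean MOVs per child: 1.07 (SD 1.17); 62.40% of children had at least one
cohort: 3335 children aged 12-47 months at 2019-12-31
fully immunized for the 14 first-year doses: 1318 (39.52%); missing only MCV-1: 339 (10.16%)
coverage declines from 96.5% (BCG-0) to 45.3% (MCV-1)
15738 visits: 5.48% at a nonassigned facility
```

Reading: the ten injected campaign dummy IDs (patient IDs used to log
mass-campaign doses, recognizable by >3 records of one dose slot) were
removed before analysis; 23.70% of visits left the child without at
least one dose it was eligible for, against a configured per-dose
withholding probability of 0.08; 5.48% of visits happened away from the
child's assigned facility against a configured movement probability of
0.055; and coverage declines monotonically along the schedule, as the
attendance stopping process implies. Each driver writes its tables
(counts alongside percentages) under `results/`.

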