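# Methods

`eirkit` implements the analysis layer of an electronic immunization
registry (EIR): given individual-level tables of patients, visits, dose
records, facilities and vaccine stock, it computes missed opportunities
for vaccination (MOV), continuum-of-care metrics, population-movement
classification, facility concentration curves, and mixed-effects
regression stages. Because no individual-level registry extract is
public, every stage is validated against a synthetic registry generator
whose data-generating process is known exactly.

## Vaccine schedule and timeliness

The national infant schedule spans six vaccines over six scheduled
visits: BCG and the OPV birth dose at birth, then OPV/Penta/PCV/Rota at
6, 10 and 14 weeks (Rota only at the first two), measles (MCV-1) at
9 months and MCV-2 at 18 months. The "full 14-dose schedule" is
everything through MCV-1 — the doses scheduled in the first year of
life. Month-valued ages are converted with a fixed constant of
30.44 days/month and rounded (9 months → 274 days, 18 months →
548 days), so scheduled dates and timeliness are reproducible regardless
of birth month; the constant and each visit age are configurable.

A dose is *timely* when given on or before its scheduled date plus a
7-day grace window (the operational defaulter threshold) and not before
its minimum age. The window is one-sided: early doses cannot occur
because a dose's minimum age defaults to its scheduled age.

## Dose eligibility and MOV detection

At each health-system contact a child is eligible for a scheduled dose
when all of the following hold: the child's age is within the dose's
[min, max] age window; the previous dose of the sequence was received at
least the minimum interval before the contact (default 28 days, the
standard programmatic minimum — the analyses this design follows do not
state a number, so it is exposed in configuration); and the dose was not
already received. Special rules: rotavirus doses are never eligible
after the first year of life (maximum age 364 days); the OPV birth dose
is only available during a configurable birth-dose window (default
14 days), after which OPV-1 becomes a valid sequence start without
OPV-0; MCV-1 requires age ≥ 274 days; BCG remains available through the
general 5-year eligibility limit.

A visit's MOV count is the number of eligible doses not administered at
it. Same-day visits by one child are merged into a single contact.
Reasons are attributed from explicit "knowingly withheld" records
(stockout, contraindication, late, refusal, expired stock); eligible
doses missed without such a record carry reason `none`. Doses withheld
for medical contraindication *count* as MOVs — matching how registry
reason tables are built — with a strict-WHO mode (`strict_who=True`)
that excludes them, since the WHO definition requires freedom from
contraindications.

The engine is validated two ways: a brute-force oracle that evaluates
each eligibility rule as an independent predicate agrees dose-for-dose
on 1,000 randomized (history, age) cases, and the full-compliance limit
(every eligible dose given at every visit) produces exactly zero MOVs on
simulated cohorts.

## Continuum of care

Cards are built per child for a cohort defined by age at a census date
(default 12–47 months at 2019-12-31; age in months is
`floor(days / 30.44)`), using live *and* back-entered doses so that
retroactively completed histories count toward coverage. Dropout
follows the first-versus-last-dose rule: Penta/PCV dropout is dose 1
without dose 3, Rota is dose 1 without dose 2, OPV starts at either
OPV-0 or OPV-1 (either is a valid sequence start) and drops out without
OPV-3, birth-to-first dropout is a birth dose with none of the visit-2
doses, and overall dropout is ≥1 dose without all 14. Children with no
doses at all never "dropped out": they are reported as a separate
zero-dose class and excluded from dropout denominators, which are
always children who received the starting dose.

The immunization typology is the binary received/not-received pattern
over the 14 first-year doses, serialized as a 14-character `R`/`N`
string in the fixed order BCG-0, OPV-0..3, Penta-1..3, PCV-1..3,
Rota-1..2, MCV-1. Counts over all keys sum to cohort size by
construction, and the two headline archetypes (all 14; all but MCV-1)
are disjoint keys whose counts equal the fully-immunized and
missing-only-MCV-1 totals.

## Population movement

A child's assigned (home) facility is fixed at registration; any visit
elsewhere is nonassigned. Nonassigned visits are banded by the
relationship between visited and assigned facility: within 5 km
(great-circle distance, Earth radius 6371 km, boundary inclusive),
beyond 5 km within the same district, another district of the same
region, or another region — administrative comparisons take precedence
over distance, and a visit to the assigned facility is `assigned` even
if another facility is closer. Facilities missing geocodes fall back to
the administrative comparison with a null distance. Facility density is
the count of other facilities within 5 km (bands 0 / 1 / 2–5 / >5);
urbanicity is ward population density ≥ 500 persons/km² at the
facility, inherited by its assigned patients.

## CQI concentration curves and stockouts

Facilities are ranked by descending issue count (ties broken by
facility ID) over the full facility universe including zero-issue
facilities; the top-q share is the head's summed count over the total,
with head size ⌈q·n⌉. An alternative mode accepts explicit printed
head counts, because published head counts do not always equal ⌈q·n⌉ of
the stated facility total and the convention cannot be recovered from a
table alone. MOV-visit issues attribute to the visited facility;
nonassigned visits and dropped-out children attribute to the child's
assigned facility. The composite stockout indicator is the percentage
of facility-vaccine-days with data whose recorded balance was zero,
over the six primary vaccines, banded half-open at <10 / 10–19 / 20–29 /
≥30%.

## Mixed-effects regression

Binary outcomes (nonassigned visit, any-MOV, dropout) are modelled with
logistic regression with nested random intercepts for region, district
and facility, encoded as concatenated keys so nesting is immune to ID
reuse. The fitting itself is delegated, never implemented here. The
default backend is lme4's `glmer` (Laplace ML) through `Rscript`:
at the zero-variance boundary its fixed effects coincide with plain
logistic regression, and its Wald SEs are well calibrated for
facility-level covariates. When R is unavailable, statsmodels'
Bayesian mixed GLM is used (Laplace posterior-mode fit by default; the
variational fit is exposed separately — it estimates variance
components well but understates fixed-effect SDs for cluster-level
covariates, so it is not the default). Failed or degenerate fits drop
the deepest nesting level and ultimately fall back to a plain logit,
always recorded in the result. CIs are Wald 95% on the log-odds scale.

Registry-scale odds ratios from any particular deployment depend on
undeposited data, so the models stage is validated purely by simulation
recovery: across 20 seeded replicates of ~5,000 visits over 50
facilities with a known facility-level log-odds (0.6) and cluster SDs
(0.1/0.1/0.3), at least 90% of fixed-effect ORs fall within 2 SEs of
truth; and in a large zero-variance simulation the mixed fit matches
plain logit within 0.01 on the OR scale.

## Synthetic registry generator

The generator emulates the statistical structure the analyses assume:
facilities in nested region→district clusters with Gaussian geocode
scatter (district spread 0.35°, facility spread 0.03°, so 5-km density
bands are non-degenerate), lognormal ward densities, facility type and
ownership mixes, and per-facility go-live dates. Children are assigned
a facility and acquire doses visit-by-visit: attendance is a stopping
process with a continuation probability per scheduled visit (defaults
0.963, 0.967, 0.869, 0.834, 0.714, 0.55 — chosen so the visit-touchpoint
curve declines like an EIR cohort's, from ~96% at birth to ~48% at the
measles visit), visit dates accumulate exponential delays (mean 4
days/visit; the birth visit is at birth), and at each attended visit
every *currently eligible* dose — computed with the same eligibility
engine the analyses use — is withheld with the configured MOV
probability (default 0.08 per dose, giving roughly a quarter of visits
an MOV; a per-visit mode is also available). Withheld doses get a
reason drawn from a distribution dominated by stockouts (52.5%), with
~46% silent (no record); stockout-reason misses force a zero-balance
ledger row for that facility-vaccine-day so the stock ledger stays
consistent. Visits relocate to a nonassigned facility with probability
0.055, destination chosen among other facilities with exp(−d/5 km)
distance decay; the movement propensity optionally carries nested
cluster random effects and an urbanicity log-odds for model-recovery
studies. Because attendance is a stopping process, the dropout rates
implied by the continuation probabilities have closed forms (recorded
in the ground truth) in the no-withholding limit, which is what the
dropout-recovery checks use.

Edge-case injection adds, with exact ground-truth tags: campaign dummy
IDs (>3 administered records of one dose slot), duplicate dose records,
back-entered-only patients, and facilities missing geocodes or stock
data — so each cleaning rule can be verified by set equality.

What the generator does *not* emulate: real spatial demography,
seasonality, facility-size heterogeneity in patient volume, missed
visits followed by returns (attendance never resumes after a gap), and
correlation between stockouts and the withholding process beyond the
forced ledger consistency. Passing recovery tests therefore shows the
estimators are correct for data satisfying the stated structure, not
that any particular registry satisfies it.

## Cleaning rules and their order

Campaign dummy IDs: any patient with more than three *administered*
records of a single (vaccine, dose number) slot is removed from all
tables (repeated explicitly-withheld records are legitimate and do not
trigger exclusion). Duplicate administered records (2–3 repeats,
assumed data-entry errors) collapse to the earliest date — first
administration is the immunologically relevant event — with a stable
tie-break on input order. Regions under a live-visit threshold by a
cutoff date can be dropped wholesale. The live-entry filter keeps only
doses logged at the time of service; the continuum variant also keeps
back-entered doses, but only for patients with at least one live
record. The canonical order is exclusion → region restriction →
entry-mode filter → dedup; exclusion and region restriction commute.

Known artifact: in live-entry mode a child whose birth doses were
back-entered looks unvaccinated at later visits, so the birth doses can
be flagged as missed opportunities the generator did not inject. The
rate-recovery tests therefore run with back-entry disabled; the default
back-entry probability (0.03) remains on for the end-to-end drivers.

## Numerical and reporting conventions

All percentages in emitted tables go through a single rounding rule —
round half up at two decimals, via exact decimal arithmetic — and every
table carries raw counts next to percentages so each printed cell is
auditable. Degenerate inputs are explicit: a zero denominator raises
rather than printing 0, an empty concentration curve is an empty result,
a facility without stock data has a null composite. Dates are ISO-8601;
all age arithmetic is in integer days.

## Problem sizes used in validation

The shipped validation suite simulates cohorts of 400–13,000 children
(up to ~52,000 visits, 48–50 facilities); the analysis drivers default
to 4,000 children. These sizes put Monte-Carlo error well below the
3-binomial-SE acceptance bands while keeping a full run in minutes on a
single core.

## Known limitations

- The OPV birth-dose window ("by the age of 2" in the source material,
  units unstated) defaults to 14 days; it is configurable and flagged.
- The minimum-interval rule (28 days) is a programmatic convention, not
  an extracted value.
- MOVs are only assessable at immunization-system contacts; contacts
  outside the registry are invisible, so MOV rates are lower bounds.
- The concentration-curve head-count convention is ambiguous in
  published tables; both conventions are exposed.
- `glmer` is invoked per fit via a subprocess; on hosts without R the
  statsmodels fallback gives slightly less calibrated SEs for
  facility-level covariates.
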