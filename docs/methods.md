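# Methods

## The costing model

`microcost` implements trial-based micro-costing ("ingredients" costing)
for paediatric HIV treatment from a provider perspective. Every resource
event on a child's case report form (CRF) — a physician or nurse visit, a
hospital admission, a medication dispense, a laboratory panel — is valued
at its unit price and summed per patient:

```
cost per patient = Σ L_i  +  Σ K_t  +  Σ D_d  +  Σ L_l
```

where `L_i` is labour cost per cadre (medical doctor, nurse), `K_t` the
apportioned share of annuitised capital (buildings, vehicles, laboratory
equipment), `D_d` medicines and supplies valued per dispensed dose, and
`L_l` laboratory diagnostics. Component definitions in a
`CostBreakdown` are **disjoint**, so the total is an exact sum:

- **physician / nursing** — number of visits × (monthly wage / monthly
  hours) × contact hours per visit. Default contact time is 0.5 h/visit
  and 160 working hours/month, both configurable.
- **medication** — outpatient dispenses only, at Σ doses × unit price.
  Drugs dispensed *during* a hospital stay are counted inside the
  inpatient component and never again here (the double-counting guard).
- **laboratory** — by default a flat per-patient panel rate (US$15),
  matching a standard panel priced identically for every child (SD 0);
  a per-test mode prices each recorded test against a lab price table.
- **inpatient** — per admission: direct in-stay medication cost plus
  length of stay × a per-bed-day overhead rate. The per-day rate bundles
  the allocated shares of laboratory, catering, administration, security,
  building and transport overheads, i.e. `inpatient = direct + overhead`.
- **outpatient** — in the breakdown, only the apportioned fixed-cost
  share of ambulatory care (its labour, drug and lab parts have their own
  columns). The stand-alone `outpatient_cost()` returns the full
  ambulatory aggregate (labour + drugs + labs + fixed share).
- **capital_share** — Σ over assets of
  `replacement_cost / a(r, n)` × allocation weight × horizon ÷ programme
  patients, where `a(r, n) = (1 − (1+r)^−n)/r` is the annuity factor
  (`= n` at `r = 0`; computed via `expm1`/`log1p` so the zero-rate limit
  is numerically continuous). Defaults: discount rate 3 %/year, useful
  life 40 years for buildings and 5 years for vehicles and laboratory
  equipment, analysis horizon 96 weeks.

Shared hospital costs use **direct allocation**: each ledger line
(administration, security, laundry, catering, utilities) is apportioned
in one step by a weight in [0, 1] — a space share (programme floor area /
facility floor area) or a patient-load share (programme admissions /
facility admissions), configurable per line. Space share is the default
basis for administration, security, utilities and buildings; patient-load
share for catering, laundry and bed space. Step-down and simultaneous
allocation are deliberate non-goals. Allocation conserves the ledger:
weights summing to 1 across programmes reproduce the ledger total to
1e-9 relative.

Price tables ship as CSV (`item_name, dosage, unit_price, category`);
the bundled ARV table prices each printed (drug, dosage) pair as **one
dose unit** (e.g. Pedimune Baby, 0.6 g, US$0.023/dose) — whether the
source prices are per tablet or per gram is not stated, so this is a
declared convention, not an inference. The bundled
opportunistic-infection drug table is price-only (its source prints
prices under a dosage header). Item lookup is case-insensitive and
whitespace-normalised; an unknown item is an error, never a silent zero.
CPI adjustment multiplies by `index(to_year)/index(from_year)`; no index
values are bundled (the CPI is an external statistic the user supplies).

**Censoring by death** truncates the event stream at the death day: no
event after it contributes, a straddling stay is clipped so it ends on
the death day, and truncating earlier can never increase any component
(monotonicity, property-tested). Missing visit data arising from death
is handled by arm-level mean imputation of the affected component
(`impute_missing_visit_costs`); the averaging level is a package choice
exposed in the API, and mean imputation preserves the complete-case mean
by construction.

All arithmetic is double precision; half-up rounding to 2 decimals
(decimal-based, applied to the shortest decimal representation) happens
only at serialisation.

## The synthetic cohort generator

No patient-level data from the underlying trials is deposited, so the
generator emulates the CRF streams the analysis assumes. Distributional
shapes are the simplest ones consistent with the published summary
statistics (which give means, ranges and caps, not distributions):

- visit counts per patient ~ Poisson (physician and nurse rates
  separately); visit days uniform over follow-up (integer day offsets
  from enrolment, day 0, closed interval);
- hospital episodes ~ Poisson; length of stay ~ lognormal rounded to
  whole days, clipped to [1, cap] with the arm's hard cap (77 days
  cotrimoxazole, 37 days ARV);
- admission causes drawn with probability proportional to the bundled
  23-condition clinical-staging frequency table (total frequency 751);
- dispenses fire per triggering event (outpatient: each physician visit;
  inpatient: each admission, optionally scaled per day of stay) with
  Poisson dose counts;
- laboratory panels (haematology, biochemistry, lymphocyte subsets,
  microbiology) at each nursing visit;
- death ~ Bernoulli(cumulative mortality), with the death day uniform
  over follow-up (only cumulative mortality is published), and the whole
  stream censored at death.

Arm presets encode the published conditions: cotrimoxazole arm n = 265,
pooled mortality 186/534, LOS cap 77, follow-up 672 days (96 weeks); ARV
arm n = 211, mortality 22/211, LOS cap 37, follow-up 336 days (48-week
schedule). The published enrolment counts upstream of randomisation are
mutually inconsistent; the presets use the randomised totals
(265 + 269 = 534), which reproduce the printed ~35 % mortality. Visit
rates and dispense means in the presets (physician 11/patient
cotrimoxazole vs 14.2 ARV, nurse 0.65 vs 8.0, admissions 1.5 vs 0.3 per
patient) are calibrated so that at the default wage schedules the mean
component costs sit near the published component means; they are single
choices, fully overridable per run.

Seeding: one master seed; each patient's substream derives from
(seed, patient index) via `SeedSequence`, so enlarging a cohort never
reshuffles earlier patients, and a fixed seed reproduces byte-identical
event tables (asserted by digest).

What the generator does **not** emulate: correlated visit/admission
processes within a child, seasonality, disease progression (CD4
trajectories, weight), loss to follow-up other than death, or
within-stay daily resource detail. Passing recovery tests therefore
shows the *pipeline* is unbiased and internally consistent under the
stated processes — not that the published per-patient totals are
reproducible, which they are not from printed inputs alone (the
published component means do not sum to the published totals either;
the engine reports component sums and leaves the discrepancy visible).

## Validation design

- **Exact published arithmetic** — the opportunistic-infection percent
  column recomputes from its 23 printed frequencies (total 751: fever
  23.44 %, diarrhoea 21.70 %, pulmonary TB 9.32 %, severe pneumonia
  10.52 %, oral candidiasis 9.85 %) and cohort mortality from printed
  counts (100×186/534 → 35 %; 100×22/211 → 10.43 %).
- **Parameter recovery** — cohorts generated with a known visit rate λ
  and per-visit cost w, zero mortality (so censoring does not bias the
  uncensored expectation), run through the full engine; the cohort mean
  labour cost is compared with λ·w within 3 standard errors, averaged
  over 20 seeds (211 or 265 patients per cohort).
- **Property suites** — annuity factor vs term-by-term summation
  (1e-9), allocation conservation, brute-force event-loop equivalence of
  `patient_total_cost` on random ≤10-event records, censoring
  monotonicity, scale equivariance, byte-identical fixed-seed reruns.

Bootstrap inference uses the percentile method (B = 10,000 default,
level 0.95, seeded). Known limitation: percentile intervals are only
first-order accurate and **undercover** for the mean of heavily skewed
small samples — Monte-Carlo calibration here puts true coverage for
lognormal(0, 1) at n = 50 near 90 % rather than the nominal 95 %.
Coverage improves with n; BCa or studentised intervals would narrow the
gap but are out of scope.

## Problem sizes used in the shipped runs

The analysis drivers run the presets at full published sizes (265/211
patients). The bootstrap coverage study uses 1,000 Monte-Carlo
replicates of n = 50 with B = 2,000 resamples; rate-recovery property
tests use 10,000-patient cohorts at small rates; OI-frequency recovery
uses 100,000 draws. The end-to-end pipeline tests run 12–15 patients per
arm with B = 200, which exercises every stage without large cohorts.
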