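# Methods

`neosurv` implements national surveillance of "brain injuries occurring at
or soon after birth" from routinely recorded neonatal-unit electronic
records: composite case ascertainment, stratified incidence estimation
against external live-birth denominators, and a range adjustment for years
in which part of the unit network did not contribute records. Because the
real registry is not publicly downloadable, the package ships a synthetic
cohort generator whose ground truth backs every test.

## Case definition and ascertainment

An infant admitted for neonatal care is a composite case if its merged
record carries at least one of seven conditions detected during the
neonatal-unit stay:

- seizures — all infants;
- intracranial haemorrhage, perinatal/neonatal stroke, hypoxic-ischaemic
  encephalopathy (HIE), central nervous system infection, bilirubin
  encephalopathy (kernicterus) — all infants;
- cystic periventricular leucomalacia (cPVL) — preterm infants
  (< 37 completed weeks) only.

Composite counts count each infant once regardless of how many conditions
are present; per-condition tables count an infant once per condition held.
Counts are reported before and after an exclusion rule: an infant whose
*only* qualifying condition is seizures, and whose record also carries a
congenital diagnosis placing the injury before birth (congenital
encephalopathy including inborn errors of metabolism, congenital infection,
congenital brain abnormality), is excluded. An infant qualifying through
any non-seizure condition is never excluded, so after-exclusion counts can
never exceed before-exclusion counts.

Raw diagnosis codes are mapped to conditions through a configurable token
catalog (`neosurv.catalog`). Real registries use controlled code lists that
are not redistributable, so the shipped catalog is a stand-in at the
granularity surveillance needs: intracranial haemorrhage carries a severe
subset (grade 3–4 intraventricular/periventricular haemorrhage, P/IVH) so
the severe-P/IVH row of the condition table can be produced, and HIE tokens
are graded (mild/moderate/severe) so ascertainment can be restricted to
moderate/severe disease by editing the catalog rather than the code — the
published surveillance definition does not resolve whether mild HIE is in
scope, so the package makes it a configuration choice. Unknown tokens are
ignored with a logged warning: surveillance must not crash on novel codes.

## Record preparation

Episode tables (one row per care episode) are cleaned before ascertainment:

- exact duplicates collapse to one row (later copies rejected with reason
  `duplicate`);
- gestational age outside 22–44 completed weeks is rejected
  (`gestation_out_of_range`); missing gestational age is retained and
  tallied in a `missing_ga` stratum downstream;
- discharge before admission is rejected (`date_interval_inverted`);
- near-duplicates (same infant, same unit, overlapping dates) are merged
  into one episode spanning both intervals with the union of codes, since
  registries merge rather than discard such rows.

Retained episodes are merged to exactly one record per infant: codes are
unioned, and gestational age and cohort year are taken from the earliest
admission (closest to birth). Gestational ages differing by more than one
week across an infant's episodes are surfaced as an inconsistency issue
while the earliest-episode value is used. The clean-then-merge composition
is idempotent, verified by property tests.

## Incidence estimation

Rates are numerator/denominator scaled to per 1 000, 10 000 or 100 000
live births. The denominator is always an external live-birth table (in
real use, national birth statistics by year and gestational-age stratum) —
a superset of the admitted population, never derived from the cohort.

95% confidence intervals use the log-transformed Poisson method: for n
observed cases the interval on the count scale is `n·exp(±1.96/√n)`. For
n = 0 the lower bound is 0 and the upper bound is the exact one-sided
Poisson limit `−ln(0.025) ≈ 3.69` expected events. This method was chosen
because it reproduces, cell for cell, the published England 2010–2015
surveillance tables from their printed numerators and denominators (41 of
48 printed cells exactly at printed precision; the remaining 7 sit on
rounding boundaries or contain typesetting slips — one printed lower bound
is a digit transposition — and no consistent Poisson or binomial interval
reproduces them; the regression tests document these individually). For
n ≥ 100 the method agrees with the exact chi-square (Garwood) interval to
within 2% on either bound. Published values are rounded half-up to the
printed decimal places; the package rounds the same way.

## Coverage-range adjustment

For a year in which a fraction of units did not contribute records, the
number of missing admissions is unknown and a point estimate would be
falsely precise. The adjustment produces a lower/upper range:

1. From the complete-coverage years, take the minimum and maximum
   year-over-year admission growth ratios.
2. Back-extrapolate the incomplete year's complete-coverage admissions
   from the first complete year: divide its admissions by the compounded
   maximum ratio over the year gap for the lower estimate, and by the
   compounded minimum ratio for the upper — assuming real growth in the
   unobserved years was no more extreme than anything seen under complete
   coverage. On the published England series this implies total 2010
   admissions between 70 315 and 76 516 against 64 375 observed, i.e.
   implied inflation factors of 1.09–1.19, consistent with roughly 10% of
   units not contributing.
3. Compute the observed case/admission proportion in the incomplete year
   and the sample SD (ddof = 1) of that proportion across complete years;
   shift the proportion down/up by two SD (floored at zero with a warning).
4. Lower adjusted cases = lower admissions × (proportion − 2 SD); upper
   adjusted cases = upper admissions × (proportion + 2 SD), rounded to
   integers before rates are taken against the live-birth denominator —
   under the assumption that the case rate among infants at
   non-contributing units does not differ from the observed rate.

The procedure is deliberately an ad hoc transparent range, not a formal
missing-data model. Its published description is loose enough to admit
several arithmetic readings and the published adjusted counts cannot be
reconstructed uniquely; the reading implemented here is the one that is
monotone, reduces to the identity under full coverage with zero SD, keeps
the lower bound above the observed count when growth is positive, and —
decisive for the choice — actually brackets the truth: in a simulation
with 10% of units masked, the range contains the true complete-cohort case
count in ≥ 90% of replicates (99/100 in the shipped study). A range built
by multiplying *observed* admissions by the raw 1.6–6% growth ratios
cannot recover ~11% missing admissions and fails that calibration, so it
was rejected. On the published series the implemented range (2 988–3 800
for 2010, after exclusions) brackets the published 3 113–3 566.

## Synthetic cohort generator

The generator emulates the registry's structure, not clinical reality.
One cohort year draws:

- a preterm/term split (default preterm fraction 0.0757) and admission
  probabilities per stratum (defaults 0.0904 term, 0.6707 preterm),
  sized so the default cohort of 664 399 live births yields ~89 000
  admissions — the scale of a recent national surveillance year;
- gestational age: term uniform on 37–41 completed weeks; preterm from a
  fixed categorical on 23–36 weighted towards late preterm, putting ~15%
  of preterm births below 32 weeks and ~30% below 34, so the subgroup
  strata used in reporting are populated;
- per-admitted-infant condition flags as independent Bernoulli draws per
  stratum, with defaults of the order of published per-condition counts;
  one deliberate dependence is modelled: P(seizures | HIE) is configurable
  (default 0.25) with the base rate solved so the marginal seizure
  prevalence stays at its configured value — this exercises counted-once
  logic without distorting prevalence recovery;
- cPVL only in preterm infants (a term cPVL prevalence other than zero is
  a config validation error);
- congenital-exclusion tokens on 2.5% of seizure cases, putting excluded
  counts at full scale in the published tables' range (tens per year);
- grade 3–4 P/IVH tokens concentrated below 32 weeks (80% of haemorrhages
  there, 25% in other preterm, 5% in term);
- uniform unit assignment over 160 units, one unit per infant; 30% of
  infants get a second, later episode at the same unit carrying a random
  subset of their codes (redundant or empty — merge must be union-safe);
- lengths of stay increasing with prematurity; dates ISO 8601 within one
  calendar year.

Dirty-record injection appends exact duplicates and corrupted *copies*
(gestational age 99, swapped dates) at configurable rates, with a sidecar
listing every injected row; because corruption copies rather than mutates,
the cleaning stage must reject exactly the sidecar and retain exactly the
original cohort — an exact oracle, used as such in tests.

What the generator does **not** model: transfers between units, mortality
and censoring, seasonal structure, unit-size heterogeneity, code-entry
error beyond the injected kinds, and any clinical correlation structure
beyond the single seizure–HIE dependence. Passing tests therefore show the
pipeline is correct under the registry's *structural* features (episodes,
duplication, coverage gaps), not that the defaults are epidemiologically
complete: in particular, independence across conditions makes the
synthetic composite count higher relative to its per-condition counts than
in real data, where co-morbidity overlap is stronger.

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of 20 000 live births (~2 500
admissions) — large enough for per-condition counts in the tens to
hundreds — with 20 seeds for prevalence recovery and 100 replicates for
the adjustment coverage study; the full-scale default cohort (664 399
births) is exercised once end to end. Monte-Carlo checks use 3-SD binomial
bands for single comparisons and 4 SD for pooled multi-condition sweeps
(14 simultaneous comparisons). Determinism: all randomness flows through
`numpy.random.default_rng` seeded from the config; a fixed seed yields
byte-identical CSV output. Ties in rounding go half-up, matching the
published tables. Degenerate inputs (zero prevalence, zero cases, empty
participating-unit sets, single-year series) either produce well-defined
zeros or raise named errors, as exercised in the unit tests.

## Known limitations

- The condition catalog is a stand-in; real deployments must supply their
  registry's code lists.
- The adjustment range is only as good as its assumptions (growth within
  observed extremes; missing units resemble contributing ones); it is a
  sensitivity range, not a confidence interval.
- Cohort-year assignment is by first admission, so injuries in a
  December-born infant admitted in January land in the later year; the
  published tables do not state their convention.
- Missing gestational age places an infant in the `all` stratum only; no
  imputation is attempted.
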