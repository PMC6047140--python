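# neosurv

National surveillance of **brain injuries occurring at or soon after
birth** from routinely recorded neonatal-unit electronic patient records.

Conditions that injure the newborn brain — hypoxic-ischaemic
encephalopathy, intracranial haemorrhage, perinatal stroke, neonatal
seizures, CNS infection, kernicterus and, in preterm infants, cystic
periventricular leucomalacia — are leading causes of neonatal death and of
lifelong morbidity such as cerebral palsy. Health systems that want to
track and reduce them need annual population incidence figures, but no
single condition captures the burden and bespoke data collection is
expensive. This package implements the alternative: a composite case
definition applied to the episode-level records that neonatal units
already enter at the point of care, with rates computed against national
live-birth denominators. It is aimed at perinatal epidemiologists and
registry analysts who need a tested, reproducible pipeline from raw
episode tables to publication-style rate tables.

## What it computes

For each cohort year, with $n$ ascertained cases and $d$ live births
(from external birth statistics, stratified by gestational age):

- **Composite incidence** $\hat\lambda = n/d \times 1000$, counting each
  infant once however many qualifying conditions it has, reported before
  and after exclusion of seizure-only cases with a congenital (pre-birth)
  diagnosis.
- **95% CIs** by the log-transformed Poisson method,
  $n\,e^{\pm 1.96/\sqrt{n}} / d$, with the exact Poisson bound
  $-\ln(0.025)/d$ when $n = 0$.
- **Per-condition incidence** at each condition's conventional scale (per
  1 000, 10 000 or 100 000 live births), counting an infant once per
  condition held, with term/preterm, <32-week and <34-week strata.
- **Coverage-adjusted ranges** for years when a fraction of neonatal units
  did not contribute records: observed admissions are back-extrapolated to
  complete coverage using the most extreme year-over-year admission growth
  seen in complete years, and the case/admission proportion is shifted by
  ±2 sample SD, giving lower/upper case counts and rate bounds instead of
  a falsely precise point estimate.

A synthetic cohort generator emulating the registry's structure (multiple
episodes per infant, duplicate and out-of-range rows, unit-level
non-participation) provides ground truth for every stage; see
`docs/methods.md` for the model and its limitations.

## Worked example

Reproduce a published-style rate cell from its counts — 3 418 composite
cases after exclusions among 664 399 live births:

```python
>>> from neosurv import rate_estimate
>>> rate_estimate(3418, 664399, scale=1000).format(2)
'5.14 (4.97 to 5.32)'
```

i.e. 5.14 brain injuries per 1 000 live births, with a 95% CI of 4.97 to
5.32 — the interval an analyst would print in a national report.

Run the full pipeline on synthetic data — five cohort years of 10 000
live births each, the first with only 90% of units contributing:

```sh
neosurv report --config pipeline.yaml --seed 9 --out rep
```

```
 year admissions live_births cases_before_exclusions exclusions cases_after_exclusions adjusted_cases rate_per_1000_after_exclusions
 2010      1,230      10,000                      45          0                     45       30 to 63                   3.00 to 6.30
 2012      1,308      10,000                      48          1                     47   Not adjusted            4.70 (3.53 to 6.26)
 2013      1,451      10,000                      54          2                     52   Not adjusted            5.20 (3.96 to 6.82)
 2014      1,402      10,000                      62          0                     62   Not adjusted            6.20 (4.83 to 7.95)
 2015      1,377      10,000                      58          0                     58   Not adjusted            5.80 (4.48 to 7.50)
```

The incomplete 2010 year gets an adjusted case-count and rate **range**
(45 observed cases, adjusted to between 30 and 63 under the procedure's
growth and variability assumptions); complete years get point rates with
CIs. Stage commands (`simulate`, `clean`, `ascertain`, `rates`, `adjust`)
expose each step separately on CSV inputs; the same functionality is
available as a library (`neosurv.generate_cohort`, `neosurv.clean_episodes`,
`neosurv.classify_cohort`, `neosurv.rate_estimate`, ...).

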