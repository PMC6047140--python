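"""Simulation studies validating the surveillance pipeline end to end.

Two reusable experiments back the package's claims:

* :func:`prevalence_recovery` — on clean synthetic cohorts the pipeline's
  per-condition counts must equal the generator's ground truth exactly, and
  pooled across seeds must match the configured prevalences within
  Monte-Carlo error.
* :func:`adjustment_coverage_study` — for an incomplete-coverage year (a
  fraction of units masked), the range adjustment should bracket the true
  complete-cohort case count in the stated share of replicates.

Problem sizes default to cohorts of 20 000 live births, large enough for
per-condition counts in the tens-to-hundreds while keeping a full study in
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .case_ascertainment import classify_cohort, count_cases
from .catalog import CONDITIONS
from .coverage_adjustment import CoverageSeries, adjust_incomplete_year
from .record_pipeline import clean_episodes, merge_to_infants
from .synthetic_cohort import CohortConfig, apply_coverage_mask, generate_cohort


def pipeline_counts(episodes: pd.DataFrame, year: int) -> pd.DataFrame:
    """Clean, merge and ascertain an episode table; return tidy counts."""
    retained, _ = clean_episodes(episodes)
    infants, _ = merge_to_infants(retained)
    results = classify_cohort(infants)
    return count_cases(results, infants, year=year)


@dataclass
class RecoveryResult:
    """Outcome of a multi-seed prevalence recovery study."""

    n_seeds: int
    exact_match: bool  # pipeline counts == ground truth on every seed
    #: per (condition, stratum): pooled observed count, expectation, binomial SD
    table: pd.DataFrame

    @property
    def max_abs_z(self) -> float:
        return float((self.table["z"]).abs().max())


def prevalence_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_live_births: int = 20_000,
) -> RecoveryResult:
    """Run the pipeline over ``n_seeds`` clean cohorts and audit recovery.

    Exactness: tidy pipeline counts equal ground-truth counts on every
    seed. Calibration: pooled per-condition counts match the configured
    per-admitted-infant prevalences; the table reports a z-score against
    the pooled binomial SD for each (condition, stratum).
    """
    pooled: dict[tuple[str, str], float] = {}
    admitted = {"term": 0, "preterm": 0}
    exact = True
    for k in range(n_seeds):
        cfg = CohortConfig(n_live_births=n_live_births, seed=base_seed + k)
        episodes, truth = generate_cohort(cfg)
        counts = pipeline_counts(episodes, cfg.year)
        tc = truth.counts()
        merged = counts.merge(
            tc, on=["year", "stratum", "measure"], suffixes=("_pipe", "_true")
        )
        if not (merged["count_pipe"] == merged["count_true"]).all():
            exact = False
        for stratum in ("term", "preterm"):
            mask = truth.infants["stratum"] == stratum
            admitted[stratum] += int(mask.sum())
            for cond in CONDITIONS:
                key = (cond, stratum)
                pooled[key] = pooled.get(key, 0) + int(
                    truth.infants.loc[mask, cond].sum()
                )
    cfg = CohortConfig(n_live_births=n_live_births, seed=base_seed)
    rows = []
    for (cond, stratum), observed in pooled.items():
        p = getattr(cfg.condition_prevalences[cond], stratum)
        n = admitted[stratum]
        expected = n * p
        sd = float(np.sqrt(n * p * (1 - p)))
        rows.append(
            {
                "condition": cond,
                "stratum": stratum,
                "observed": observed,
                "expected": expected,
                "sd": sd,
                "z": (observed - expected) / sd if sd > 0 else 0.0,
            }
        )
    return RecoveryResult(n_seeds=n_seeds, exact_match=exact, table=pd.DataFrame(rows))


@dataclass
class CoverageStudyResult:
    """Outcome of the incomplete-coverage adjustment simulation."""

    n_replicates: int
    n_contained: int
    replicates: pd.DataFrame  # per replicate: true count, low, high, contained

    @property
    def coverage(self) -> float:
        return self.n_contained / self.n_replicates


def adjustment_coverage_study(
    n_replicates: int = 100,
    base_seed: int = 0,
    n_live_births: int = 20_000,
    masked_fraction: float = 0.10,
    annual_growth: float = 1.02,
    n_units: int = 20,
) -> CoverageStudyResult:
    """Does the adjusted range bracket the true complete-cohort count?

    Each replicate simulates one incomplete target year (two years before
    the first complete year, ``masked_fraction`` of units not contributing)
    and four complete-coverage years whose admission probabilities grow by
    ``annual_growth`` per year. The target year's full pipeline runs on the
    masked records; complete years contribute their observed admissions and
    case counts; the range adjustment is applied and compared with the true
    (unmasked) after-exclusion composite count.
    """
    rows = []
    for rep in range(n_replicates):
        seed0 = base_seed + 1000 * rep
        admissions: dict[int, int] = {}
        cases: dict[int, int] = {}
        # complete-coverage years 2012-2015
        for i, year in enumerate([2012, 2013, 2014, 2015]):
            cfg = CohortConfig(
                year=year,
                n_live_births=n_live_births,
                n_units=n_units,
                seed=seed0 + i,
                admission_prob_term=min(1.0, 0.0904 * annual_growth ** (i + 2)),
                admission_prob_preterm=min(1.0, 0.6707 * annual_growth ** (i + 2)),
            )
            _, truth = generate_cohort(cfg)
            admissions[year] = len(truth.infants)
            cases[year] = int(truth.infants["composite_after"].sum())
        # incomplete target year 2010, full pipeline on masked records
        cfg0 = CohortConfig(
            year=2010,
            n_live_births=n_live_births,
            n_units=n_units,
            seed=seed0 + 7,
        )
        episodes, truth0 = generate_cohort(cfg0)
        true_count = int(truth0.infants["composite_after"].sum())
        rng = np.random.default_rng(seed0 + 13)
        units = sorted(episodes["unit_id"].unique())
        n_keep = max(1, int(round(len(units) * (1.0 - masked_fraction))))
        participating = set(rng.choice(units, size=n_keep, replace=False))
        observed = apply_coverage_mask(episodes, participating)
        counts = pipeline_counts(observed, 2010)
        cidx = counts.set_index(["stratum", "measure"])["count"]
        obs_infants = merge_to_infants(clean_episodes(observed)[0])[0]
        admissions[2010] = len(obs_infants)
        cases[2010] = int(cidx.loc[("all", "composite_after")])
        series = CoverageSeries(
            admissions=admissions,
            cases=cases,
            complete_years=frozenset({2012, 2013, 2014, 2015}),
            target_year=2010,
            live_births=n_live_births,
        )
        adj = adjust_incomplete_year(series)
        contained = adj.adjusted_cases_low <= true_count <= adj.adjusted_cases_high
        rows.append(
            {
                "replicate": rep,
                "true_count": true_count,
                "low": adj.adjusted_cases_low,
                "high": adj.adjusted_cases_high,
                "contained": contained,
            }
        )
    df = pd.DataFrame(rows)
    return CoverageStudyResult(
        n_replicates=n_replicates,
        n_contained=int(df["contained"].sum()),
        replicates=df,
    )
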