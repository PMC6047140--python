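"""Range adjustment for surveillance years with incomplete registry coverage.

In years when a fraction of neonatal units did not contribute records, the
observed admission and case counts undersell the national totals, and the
number of missing admissions is unknown. The adjustment produces a
lower/upper range instead of a point estimate:

1. From the complete-coverage years, take the most extreme year-over-year
   admission growth ratios (min and max).
2. Estimate the incomplete year's complete-coverage admissions by deflating
   the first complete year's admissions back over the year gap — by the
   maximum growth ratio for the lower admissions estimate and by the
   minimum ratio for the upper — assuming true growth in the unobserved
   years was no more extreme than anything seen under complete coverage.
3. Compute the observed case/admission proportion in the incomplete year
   and the sample SD of that proportion across complete years; shift the
   proportion down/up by two SD for the lower/upper branch.
4. Lower adjusted cases = lower admissions x (proportion - 2 SD); upper
   adjusted cases = upper admissions x (proportion + 2 SD); rates divide
   the adjusted counts by the external live-birth denominator, under the
   assumption that the case rate among missing infants does not differ
   from the observed rate.

The adjustment is deliberately ad hoc (a transparent range, not a formal
missing-data model); its calibration is checked by simulation in the test
suite.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Mapping

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverageSeries:
    """Observed admissions/cases by year plus coverage metadata.

    ``complete_years`` must contain at least two consecutive years;
    ``target_year`` is the incomplete-coverage year to adjust;
    ``live_births`` is the external denominator for the target year.
    """

    admissions: Mapping[int, int]
    cases: Mapping[int, int]
    complete_years: frozenset[int]
    target_year: int
    live_births: int

    def __post_init__(self):
        years = sorted(self.complete_years)
        if len(years) < 2:
            raise ValueError("need at least two complete-coverage years")
        if years != list(range(years[0], years[-1] + 1)):
            raise ValueError("complete_years must be consecutive")
        if self.target_year >= years[0]:
            raise ValueError("target_year must precede the complete-coverage years")
        for y in list(years) + [self.target_year]:
            if y not in self.admissions or y not in self.cases:
                raise ValueError(f"missing admissions/cases for year {y}")
            if self.cases[y] > self.admissions[y]:
                raise ValueError(f"cases exceed admissions in {y}")
        if self.live_births <= 0:
            raise ValueError("live_births must be positive")


@dataclass(frozen=True)
class AdjustmentEstimate:
    """Lower/upper adjusted case counts and rates per 1000 live births."""

    year: int
    inflation_low: float
    inflation_high: float
    adjusted_cases_low: int
    adjusted_cases_high: int
    rate_low: float
    rate_high: float

    def format_range(self, decimals: int = 2) -> str:
        fmt = f"{{:.{decimals}f}}"
        return f"{fmt.format(self.rate_low)} to {fmt.format(self.rate_high)}"


def yearly_increase_bounds(
    admissions_by_year: Mapping[int, int]
) -> tuple[float, float]:
    """Min and max year-over-year admission ratios across consecutive years."""
    years = sorted(admissions_by_year)
    if len(years) < 2:
        raise ValueError("need at least two years of admissions")
    if years != list(range(years[0], years[-1] + 1)):
        raise ValueError("years must be consecutive")
    ratios = [
        admissions_by_year[y] / admissions_by_year[y - 1] for y in years[1:]
    ]
    return min(ratios), max(ratios)


def proportion_sd(
    cases_by_year: Mapping[int, int], admissions_by_year: Mapping[int, int]
) -> float:
    """Sample SD of the per-year case/admission proportion."""
    years = sorted(cases_by_year)
    if sorted(admissions_by_year) != years:
        raise ValueError("cases and admissions must cover the same years")
    if len(years) < 2:
        raise ValueError("need at least two years to estimate an SD")
    props = [cases_by_year[y] / admissions_by_year[y] for y in years]
    return statistics.stdev(props)


def adjust_incomplete_year(series: CoverageSeries) -> AdjustmentEstimate:
    """Adjusted case-count range and rate range for an incomplete year."""
    complete = sorted(series.complete_years)
    adm_complete = {y: series.admissions[y] for y in complete}
    cases_complete = {y: series.cases[y] for y in complete}
    r_min, r_max = yearly_increase_bounds(adm_complete)
    sd = proportion_sd(cases_complete, adm_complete)

    gap = complete[0] - series.target_year
    anchor = series.admissions[complete[0]]
    est_adm_low = anchor / (r_max**gap)
    est_adm_high = anchor / (r_min**gap)

    obs_adm = series.admissions[series.target_year]
    obs_cases = series.cases[series.target_year]
    p = obs_cases / obs_adm
    p_low = p - 2.0 * sd
    if p_low < 0.0:
        logger.warning(
            "proportion - 2*SD below zero for %s; flooring at 0", series.target_year
        )
        p_low = 0.0
    p_high = p + 2.0 * sd

    cases_low = round(est_adm_low * p_low)
    cases_high = round(est_adm_high * p_high)
    return AdjustmentEstimate(
        year=series.target_year,
        inflation_low=est_adm_low / obs_adm,
        inflation_high=est_adm_high / obs_adm,
        adjusted_cases_low=int(cases_low),
        adjusted_cases_high=int(cases_high),
        rate_low=cases_low / series.live_births * 1000.0,
        rate_high=cases_high / series.live_births * 1000.0,
    )
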