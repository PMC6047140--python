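"""Incidence rates per live births with 95% confidence intervals.

Rates are numerator/denominator scaled to per 1 000, 10 000 or 100 000 live
births. Confidence intervals use the log-transformed Poisson method: with n
observed cases, the interval on the count scale is ``n * exp(+/- 1.96 /
sqrt(n))``, divided by the denominator and scaled. For n = 0 the lower
bound is 0 and the upper bound is the exact one-sided Poisson limit
``-ln(0.025) / d`` (~3.69 expected events). The denominator is always an
external live-birth count — a superset of the admitted population — never
derived from the cohort itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

Z_95 = 1.96
#: Exact Poisson 97.5% upper bound on the mean when zero events are observed.
ZERO_COUNT_UPPER = -math.log(0.025)

VALID_SCALES = (1_000, 10_000, 100_000)


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero, as published tables are rounded."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(f"{x:.12f}").quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class IncidenceEstimate:
    """A point rate and 95% CI on a per-``scale``-live-births scale."""

    numerator: int
    denominator: int
    scale: int
    rate: float
    ci_low: float
    ci_high: float
    method: str = "poisson_log"

    def rounded(self, decimals: int) -> tuple[float, float, float]:
        return (
            round_half_up(self.rate, decimals),
            round_half_up(self.ci_low, decimals),
            round_half_up(self.ci_high, decimals),
        )

    def format(self, decimals: int) -> str:
        r, lo, hi = self.rounded(decimals)
        fmt = f"{{:.{decimals}f}}"
        return f"{fmt.format(r)} ({fmt.format(lo)} to {fmt.format(hi)})"


def rate_estimate(
    numerator: int, denominator: int, scale: int = 1_000
) -> IncidenceEstimate:
    """Point rate and log-transformed Poisson 95% CI.

    ``numerator`` is a case count, ``denominator`` a live-birth count,
    ``scale`` the reporting scale (per 1 000 / 10 000 / 100 000 births).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    if numerator > denominator:
        raise ValueError("numerator exceeds denominator")
    if scale not in VALID_SCALES:
        raise ValueError(f"scale must be one of {VALID_SCALES}")
    rate = numerator / denominator * scale
    if numerator == 0:
        lo, hi = 0.0, ZERO_COUNT_UPPER / denominator * scale
    else:
        half = Z_95 / math.sqrt(numerator)
        lo = numerator * math.exp(-half) / denominator * scale
        hi = numerator * math.exp(half) / denominator * scale
    return IncidenceEstimate(
        numerator=int(numerator),
        denominator=int(denominator),
        scale=scale,
        rate=rate,
        ci_low=lo,
        ci_high=hi,
    )


class DenominatorTable:
    """Live births by (year, stratum); strata: all/term/preterm/lt32/lt34.

    Backed by a tidy frame with columns ``year, stratum, live_births``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"year", "stratum", "live_births"}
        if not required <= set(table.columns):
            raise ValueError(f"denominator table needs columns {sorted(required)}")
        t = table.copy()
        t["year"] = t["year"].astype(int)
        t["live_births"] = t["live_births"].astype(int)
        if (t["live_births"] <= 0).any():
            raise ValueError("live_births must be positive")
        if t.duplicated(["year", "stratum"]).any():
            raise ValueError("duplicate (year, stratum) rows")
        for year, g in t.groupby("year"):
            s = g.set_index("stratum")["live_births"]
            if {"all", "term", "preterm"} <= set(s.index):
                if s["term"] + s["preterm"] > s["all"]:
                    raise ValueError(
                        f"term + preterm exceeds all live births in {year}"
                    )
        self._table = t
        self._index = t.set_index(["year", "stratum"])["live_births"]

    @classmethod
    def from_csv(cls, path) -> "DenominatorTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_records(cls, records: list[dict]) -> "DenominatorTable":
        return cls(pd.DataFrame(records))

    def lookup(self, year: int, stratum: str) -> int:
        try:
            return int(self._index.loc[(int(year), stratum)])
        except KeyError:
            raise KeyError(
                f"no live-birth denominator for (year={year}, stratum={stratum!r})"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return self._table.copy()


def rates_for_cohort(
    counts: pd.DataFrame,
    denominators: DenominatorTable,
    requests: list[tuple[str, str, int]],
) -> pd.DataFrame:
    """One incidence estimate per requested (measure, stratum, scale).

    ``counts`` is the tidy frame from :func:`~neosurv.case_ascertainment.
    count_cases` (columns ``year, stratum, measure, count``), possibly
    spanning several years. Missing denominators raise a KeyError naming
    the (year, stratum) pair.
    """
    idx = counts.set_index(["year", "stratum", "measure"])["count"]
    rows = []
    for year in sorted(counts["year"].unique()):
        for measure, stratum, scale in requests:
            try:
                n = int(idx.loc[(year, stratum, measure)])
            except KeyError:
                raise KeyError(
                    f"no count for (year={year}, stratum={stratum!r}, "
                    f"measure={measure!r})"
                ) from None
            d = denominators.lookup(year, stratum)
            est = rate_estimate(n, d, scale)
            rows.append(
                {
                    "year": int(year),
                    "measure": measure,
                    "stratum": stratum,
                    "n": est.numerator,
                    "d": est.denominator,
                    "scale": scale,
                    "rate": est.rate,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "method": est.method,
                }
            )
    return pd.DataFrame(rows)
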