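"""Publication-style surveillance tables and the end-to-end pipeline driver.

A surveillance report has two faces: a per-year summary (admissions, live
births, composite case counts before/after exclusions, and either a rate
with 95% CI for complete-coverage years or an adjusted range for incomplete
ones — never both), and a per-condition table with stratified counts and
scaled rates. Output is written both as machine-readable CSV and as
aligned human-readable text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field
import pandas as pd

from .case_ascertainment import classify_cohort, count_cases, default_catalog
from .catalog import CONDITIONS, ConditionCatalog
from .coverage_adjustment import AdjustmentEstimate, CoverageSeries, adjust_incomplete_year
from .incidence_stats import DenominatorTable, rate_estimate, rates_for_cohort, round_half_up
from .record_pipeline import clean_episodes, merge_to_infants
from .synthetic_cohort import (
    CohortConfig,
    apply_coverage_mask,
    generate_cohort,
    inject_dirty_records,
)

logger = logging.getLogger(__name__)

#: (measure, stratum, scale, decimals) rows of the default condition table.
CONDITION_TABLE_SPEC: tuple[tuple[str, str, int, int], ...] = tuple(
    (cond, "all", 100_000 if cond == "bilirubin_encephalopathy" else 1_000, 1)
    for cond in CONDITIONS
)


@dataclass
class SurveillanceReport:
    """Assembled surveillance tables, ready to render or persist."""

    summary: pd.DataFrame
    conditions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_text(self) -> str:
        lines = ["Composite brain-injury surveillance summary", ""]
        lines.append(_render_frame(self.summary))
        if len(self.conditions):
            lines += ["", "Per-condition incidence", ""]
            lines.append(_render_frame(self.conditions))
        return "\n".join(lines) + "\n"

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(outdir / "summary.csv", index=False)
        if len(self.conditions):
            self.conditions.to_csv(outdir / "conditions.csv", index=False)
        (outdir / "report.txt").write_text(self.to_text(), encoding="utf-8")


def _render_frame(df: pd.DataFrame) -> str:
    d = df.copy()
    for col in d.columns:
        if col != "year" and pd.api.types.is_integer_dtype(d[col]):
            d[col] = d[col].map(lambda v: f"{v:,}")
    return d.to_string(index=False)


def build_report(
    counts: pd.DataFrame,
    estimates: pd.DataFrame,
    adjustments: dict[int, AdjustmentEstimate],
    denominators: DenominatorTable,
    admissions_by_year: Optional[dict[int, int]] = None,
) -> SurveillanceReport:
    """Assemble per-year summary and per-condition tables.

    ``counts`` is the tidy count frame (all years); ``estimates`` the rate
    frame from :func:`rates_for_cohort` for complete-coverage years;
    ``adjustments`` maps incomplete years to their range estimates. A year
    must appear with a CI or a range, never both.
    """
    idx = counts.set_index(["year", "stratum", "measure"])["count"]
    years = sorted(counts["year"].unique())
    est_idx = (
        estimates.set_index(["year", "measure", "stratum"])
        if len(estimates)
        else None
    )
    rows = []
    for year in years:
        year = int(year)
        has_ci = est_idx is not None and (year, "composite_after", "all") in est_idx.index
        has_range = year in adjustments
        if has_ci and has_range:
            raise ValueError(f"year {year} has both a CI estimate and an adjustment")
        before = int(idx.loc[(year, "all", "composite_before")])
        after = int(idx.loc[(year, "all", "composite_after")])
        row = {
            "year": year,
            "admissions": (admissions_by_year or {}).get(year, pd.NA),
            "live_births": denominators.lookup(year, "all"),
            "cases_before_exclusions": before,
            "exclusions": before - after,
            "cases_after_exclusions": after,
            "adjusted_cases": "Not adjusted",
            "rate_per_1000_after_exclusions": "",
        }
        if has_range:
            adj = adjustments[year]
            row["adjusted_cases"] = (
                f"{adj.adjusted_cases_low} to {adj.adjusted_cases_high}"
            )
            row["rate_per_1000_after_exclusions"] = adj.format_range(2)
        elif has_ci:
            e = est_idx.loc[(year, "composite_after", "all")]
            est = rate_estimate(int(e["n"]), int(e["d"]), int(e["scale"]))
            row["rate_per_1000_after_exclusions"] = est.format(2)
        else:
            row["rate_per_1000_after_exclusions"] = "missing"
        rows.append(row)
    summary = pd.DataFrame(rows)

    cond_rows = []
    for year in years:
        year = int(year)
        if year in adjustments:
            continue  # per-condition rates only under complete coverage
        for measure, stratum, scale, decimals in CONDITION_TABLE_SPEC:
            try:
                n = int(idx.loc[(year, stratum, measure)])
                d = denominators.lookup(year, stratum)
            except KeyError:
                cond_rows.append(
                    {"year": year, "condition": measure, "stratum": stratum,
                     "n": pd.NA, "rate_display": "missing"}
                )
                continue
            est = rate_estimate(n, d, scale)
            cond_rows.append(
                {
                    "year": year,
                    "condition": measure,
                    "stratum": stratum,
                    "n": n,
                    "scale": scale,
                    "rate_display": est.format(decimals),
                }
            )
    conditions = pd.DataFrame(cond_rows)
    return SurveillanceReport(summary=summary, conditions=conditions)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


class YearSpec(BaseModel):
    """One cohort year of a pipeline run."""

    cohort: CohortConfig
    complete: bool = True
    participating_fraction: float = Field(default=1.0, gt=0.0, le=1.0)
    dup_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    out_of_range_rate: float = Field(default=0.0, ge=0.0, le=1.0)


class PipelineConfig(BaseModel):
    """Declarative configuration of a full surveillance run."""

    years: list[YearSpec]
    #: optional explicit denominator rows (year, stratum, live_births);
    #: defaults to the generator's true live-birth counts.
    denominators: Optional[list[dict]] = None
    catalog_path: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))


def run_pipeline(
    config: PipelineConfig,
    seed: Optional[int] = None,
    outdir=None,
    catalog: Optional[ConditionCatalog] = None,
) -> SurveillanceReport:
    """simulate -> clean/merge -> ascertain -> rates -> adjust -> report.

    ``seed``, when given, overrides each year's cohort seed (offset by the
    year index) so a whole run is reproducible from one integer. Stage-level
    record counts are logged; any stage failure propagates with its cause.
    """
    if catalog is None:
        catalog = (
            ConditionCatalog.from_yaml(config.catalog_path)
            if config.catalog_path
            else default_catalog()
        )
    all_counts = []
    admissions: dict[int, int] = {}
    cases_after: dict[int, int] = {}
    denom_rows: list[dict] = []
    complete_years: set[int] = set()
    incomplete_years: list[int] = []
    for i, ys in enumerate(config.years):
        cohort_cfg = ys.cohort
        if seed is not None:
            cohort_cfg = cohort_cfg.model_copy(update={"seed": int(seed) + i})
        year = cohort_cfg.year
        episodes, truth = generate_cohort(cohort_cfg)
        logger.info("year %s: generated %d episodes", year, len(episodes))
        if ys.dup_rate or ys.out_of_range_rate:
            episodes, _ = inject_dirty_records(
                episodes, ys.dup_rate, ys.out_of_range_rate, cohort_cfg.seed + 101
            )
        if ys.participating_fraction < 1.0:
            rng = np.random.default_rng(cohort_cfg.seed + 211)
            units = sorted(episodes["unit_id"].unique())
            k = max(1, int(round(len(units) * ys.participating_fraction)))
            participating = set(rng.choice(units, size=k, replace=False))
            episodes = apply_coverage_mask(episodes, participating)
            logger.info(
                "year %s: coverage mask kept %d/%d units", year, k, len(units)
            )
        retained, rejects = clean_episodes(episodes)
        logger.info(
            "year %s: cleaned %d -> %d episodes (%d rejected)",
            year, len(episodes), len(retained), len(rejects),
        )
        infants, issues = merge_to_infants(retained)
        logger.info("year %s: merged to %d infants", year, len(infants))
        results = classify_cohort(infants, catalog)
        counts = count_cases(results, infants, year=year)
        all_counts.append(counts)
        admissions[year] = len(infants)
        cidx = counts.set_index(["stratum", "measure"])["count"]
        cases_after[year] = int(cidx.loc[("all", "composite_after")])
        if ys.complete:
            complete_years.add(year)
        else:
            incomplete_years.append(year)
        for stratum in ("all", "term", "preterm"):
            denom_rows.append(
                {
                    "year": year,
                    "stratum": stratum,
                    "live_births": truth.live_births[stratum],
                }
            )
    counts = pd.concat(all_counts, ignore_index=True)
    denominators = (
        DenominatorTable.from_records(config.denominators)
        if config.denominators
        else DenominatorTable.from_records(denom_rows)
    )

    requests = [
        ("composite_after", "all", 1_000),
        ("composite_before", "all", 1_000),
        ("composite_after", "term", 1_000),
        ("composite_after", "preterm", 1_000),
    ]
    complete_counts = counts[counts["year"].isin(sorted(complete_years))]
    estimates = (
        rates_for_cohort(complete_counts, denominators, requests)
        if len(complete_counts)
        else pd.DataFrame()
    )

    adjustments: dict[int, AdjustmentEstimate] = {}
    for year in incomplete_years:
        series = CoverageSeries(
            admissions=admissions,
            cases=cases_after,
            complete_years=frozenset(complete_years),
            target_year=year,
            live_births=denominators.lookup(year, "all"),
        )
        adjustments[year] = adjust_incomplete_year(series)

    report = build_report(counts, estimates, adjustments, denominators, admissions)
    if outdir is not None:
        report.write(outdir)
        counts.to_csv(Path(outdir) / "counts.csv", index=False)
        if len(estimates):
            estimates.to_csv(Path(outdir) / "estimates.csv", index=False)
    return report
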