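"""Composite case ascertainment for neonatal brain injury surveillance.

An infant is a composite case if it holds at least one of seven conditions
(seizures; intracranial haemorrhage; perinatal/neonatal stroke;
hypoxic-ischaemic encephalopathy; CNS infection; bilirubin encephalopathy;
and, in preterm infants only, cystic periventricular leucomalacia), counted
once regardless of how many conditions are present. Counts are also
reported before and after an exclusion rule: infants whose *only* qualifying
condition is seizures, and whose record also carries a congenital diagnosis
indicating that the injury predated birth, are excluded. Infants qualifying
via any non-seizure condition are never excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .catalog import (  # noqa: F401  (ConditionCatalog re-exported here by design)
    CONDITIONS,
    STRATA,
    TERM_WEEKS,
    ConditionCatalog,
    ConditionDef,
    default_catalog,
    parse_codes,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AscertainmentResult:
    """Per-infant condition flags and composite case status."""

    infant_id: str
    flags: dict[str, bool]
    severe_pivh: bool
    composite_before_exclusions: bool
    composite_after_exclusions: bool
    excluded: bool
    exclusion_reason: str | None = None


def _condition_flag(
    codes: frozenset[str], cdef: ConditionDef, gestational_weeks: float | None
) -> bool:
    if cdef.restriction == "preterm_only":
        ga = gestational_weeks
        if ga is None or ga != ga or ga >= TERM_WEEKS:
            return False
    return not codes.isdisjoint(cdef.tokens)


def _warn_unknown(codes: frozenset[str], catalog: ConditionCatalog) -> None:
    unknown = codes - catalog.known_tokens
    if unknown:
        logger.warning("ignoring unknown catalog tokens: %s", sorted(unknown))


def classify_infant(
    infant: pd.Series | dict, catalog: ConditionCatalog
) -> AscertainmentResult:
    """Classify one merged infant record against the catalog.

    Each flag is true iff the infant's code set intersects that condition's
    token set and the infant satisfies the condition's population
    restriction. Unknown tokens are ignored with a logged warning —
    surveillance must not crash on novel codes. The exclusion rule is
    applied before returning.
    """
    codes = parse_codes(infant["codes"])
    _warn_unknown(codes, catalog)
    ga = infant.get("gestational_weeks")
    flags = {
        cond: _condition_flag(codes, cdef, ga)
        for cond, cdef in catalog.conditions.items()
    }
    severe = not codes.isdisjoint(
        catalog.conditions["intracranial_haemorrhage"].severe_tokens
    )
    composite = any(flags.values())
    result = AscertainmentResult(
        infant_id=str(infant["infant_id"]),
        flags=flags,
        severe_pivh=severe,
        composite_before_exclusions=composite,
        composite_after_exclusions=composite,
        excluded=False,
    )
    return apply_exclusion_rule(result, infant, catalog)


def apply_exclusion_rule(
    result: AscertainmentResult, infant: pd.Series | dict, catalog: ConditionCatalog
) -> AscertainmentResult:
    """Exclude seizure-only cases carrying a congenital (pre-birth) diagnosis.

    ``composite_after = composite_before AND NOT (seizures is the only
    qualifying condition AND the code set intersects the exclusion set)``.
    """
    codes = parse_codes(infant["codes"])
    seizure_only = result.flags.get("seizures", False) and not any(
        v for k, v in result.flags.items() if k != "seizures"
    )
    hit = codes & catalog.exclusion_tokens
    excluded = bool(result.composite_before_exclusions and seizure_only and hit)
    return replace(
        result,
        excluded=excluded,
        exclusion_reason=(
            f"congenital diagnosis {sorted(hit)} with seizures as only basis"
            if excluded
            else None
        ),
        composite_after_exclusions=result.composite_before_exclusions and not excluded,
    )


def classify_cohort(
    infants: pd.DataFrame, catalog: ConditionCatalog | None = None
) -> pd.DataFrame:
    """Vectorised classification of a merged-infant table.

    Returns one row per infant: boolean columns per condition, plus
    ``severe_pivh``, ``excluded``, ``composite_before`` and
    ``composite_after``.
    """
    catalog = catalog or default_catalog()
    code_sets = infants["codes"].map(parse_codes)
    all_seen: set[str] = set().union(*code_sets) if len(code_sets) else set()
    _warn_unknown(frozenset(all_seen), catalog)

    ga = pd.to_numeric(infants["gestational_weeks"], errors="coerce")
    out = pd.DataFrame({"infant_id": infants["infant_id"].astype(str)})
    for cond, cdef in catalog.conditions.items():
        flag = code_sets.map(lambda s, t=cdef.tokens: not s.isdisjoint(t))
        if cdef.restriction == "preterm_only":
            flag &= (ga < TERM_WEEKS).fillna(False)
        out[cond] = flag.to_numpy(dtype=bool)
    sev = catalog.conditions["intracranial_haemorrhage"].severe_tokens
    out["severe_pivh"] = code_sets.map(lambda s: not s.isdisjoint(sev)).to_numpy(bool)

    others = [c for c in catalog.conditions if c != "seizures"]
    any_other = out[others].any(axis=1)
    composite_before = out["seizures"] | any_other
    has_excl = code_sets.map(
        lambda s: not s.isdisjoint(catalog.exclusion_tokens)
    ).to_numpy(bool)
    excluded = out["seizures"] & ~any_other & has_excl
    out["excluded"] = excluded
    out["composite_before"] = composite_before
    out["composite_after"] = composite_before & ~excluded
    return out


def count_cases(
    results: pd.DataFrame, infants: pd.DataFrame, year: int | None = None
) -> pd.DataFrame:
    """Stratified counts of composite and per-condition cases.

    Composite measures count each infant once; per-condition measures count
    an infant once per condition held. Strata: ``all``, ``term`` (>=37
    weeks), ``preterm`` (<37), ``lt32``, ``lt34``, and ``missing_ga``
    (gestational age absent; such infants appear in ``all`` and
    ``missing_ga`` only). Returns a tidy frame with columns
    ``year, stratum, measure, count``.
    """
    if len(results) != len(infants):
        raise ValueError("results and infants must align one-to-one")
    merged = results.merge(
        infants[["infant_id", "gestational_weeks"]].assign(
            infant_id=lambda d: d["infant_id"].astype(str)
        ),
        on="infant_id",
        validate="one_to_one",
    )
    if year is None:
        year = int(infants["year"].iloc[0]) if "year" in infants and len(infants) else -1
    ga = pd.to_numeric(merged["gestational_weeks"], errors="coerce")
    strata = {
        "all": pd.Series(True, index=merged.index),
        "term": ga >= TERM_WEEKS,
        "preterm": ga < TERM_WEEKS,
        "lt32": ga < 32,
        "lt34": ga < 34,
        "missing_ga": ga.isna(),
    }
    measures = list(CONDITIONS) + [
        "severe_pivh",
        "excluded",
        "composite_before",
        "composite_after",
    ]
    rows = []
    for stratum, mask in strata.items():
        for m in measures:
            rows.append(
                {
                    "year": year,
                    "stratum": stratum,
                    "measure": m,
                    "count": int(merged.loc[mask, m].sum()),
                }
            )
    return pd.DataFrame(rows)


def results_to_frame(results: list[AscertainmentResult]) -> pd.DataFrame:
    """Convert per-infant results into the frame layout of classify_cohort."""
    rows = []
    for r in results:
        row = {"infant_id": r.infant_id, **r.flags}
        row["severe_pivh"] = r.severe_pivh
        row["excluded"] = r.excluded
        row["composite_before"] = r.composite_before_exclusions
        row["composite_after"] = r.composite_after_exclusions
        rows.append(row)
    return pd.DataFrame(rows)
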