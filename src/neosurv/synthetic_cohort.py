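"""Synthetic neonatal-unit cohort generator with known ground truth.

Emulates the structure of a national neonatal registry formed from
episode-level electronic patient records: a cohort year of live births, a
gestational-age-dependent probability of neonatal-unit admission, multiple
care episodes per admitted infant with consistent infant-level fields,
per-admitted-infant condition prevalences by term/preterm stratum,
congenital-exclusion diagnoses attached to a fraction of seizure cases,
unit-level non-participation for incomplete-coverage years, and injectable
dirty records (exact duplicates, impossible values).

Every cohort is accompanied by a :class:`GroundTruth` object recording the
true per-infant condition flags and the true stratified counts, so each
downstream pipeline stage can be tested against a known answer without any
real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .catalog import CONDITIONS, TERM_WEEKS, format_codes

#: Column order of the episode CSV dialect.
EPISODE_COLUMNS: tuple[str, ...] = (
    "infant_id",
    "unit_id",
    "year",
    "admission_date",
    "discharge_date",
    "gestational_weeks",
    "codes",
)

# Preterm gestational-age distribution (completed weeks 23-36), weighted
# towards late preterm so that ~15% of preterm births fall below 32 weeks
# and ~30% below 34 weeks, matching the stratum sizes national birth
# statistics imply.
_PRETERM_WEEKS = np.arange(23, 37)
_PRETERM_WEIGHTS = np.array(
    [0.3, 0.4, 0.5, 0.6, 0.7, 1.0, 1.2, 1.5, 1.8, 3.5, 5.0, 8.0, 12.0, 18.0]
)
_PRETERM_WEIGHTS = _PRETERM_WEIGHTS / _PRETERM_WEIGHTS.sum()

_EXCLUSION_TOKENS = ("CONG_ENCEPH", "IEM", "CONG_INF", "CONG_BRAIN_ABN")


class StratumPrevalence(BaseModel):
    """Per-admitted-infant probability of a condition, by birth stratum."""

    term: float = Field(ge=0.0, le=1.0)
    preterm: float = Field(ge=0.0, le=1.0)


def _default_prevalences() -> dict[str, StratumPrevalence]:
    # Magnitudes chosen to emulate national per-condition case counts among
    # ~55k term and ~34k preterm admissions in a recent surveillance year.
    return {
        "seizures": StratumPrevalence(term=0.0167, preterm=0.0098),
        "intracranial_haemorrhage": StratumPrevalence(term=0.0021, preterm=0.0181),
        "stroke": StratumPrevalence(term=0.0014, preterm=0.0004),
        "hie": StratumPrevalence(term=0.0257, preterm=0.0096),
        "cns_infection": StratumPrevalence(term=0.0050, preterm=0.0056),
        "bilirubin_encephalopathy": StratumPrevalence(term=0.00007, preterm=0.00005),
        "cpvl": StratumPrevalence(term=0.0, preterm=0.0055),
    }


class CohortConfig(BaseModel):
    """Parameters of one synthetic cohort year.

    Defaults emulate a recent national surveillance year in England:
    ~664k live births, ~7.5% preterm, admission probabilities yielding
    ~89k neonatal-unit admissions, and condition prevalences of the order
    observed among admitted infants.
    """

    year: int = 2015
    n_live_births: int = Field(default=664_399, gt=0)
    preterm_fraction: float = Field(default=0.0757, ge=0.0, le=1.0)
    admission_prob_term: float = Field(default=0.0904, ge=0.0, le=1.0)
    admission_prob_preterm: float = Field(default=0.6707, ge=0.0, le=1.0)
    condition_prevalences: dict[str, StratumPrevalence] = Field(
        default_factory=_default_prevalences
    )
    #: P(seizures | HIE) within stratum; the marginal seizure prevalence is
    #: preserved at its configured value, so this only shapes co-occurrence.
    seizure_given_hie: float = Field(default=0.25, ge=0.0, le=1.0)
    exclusion_prob_given_seizure: float = Field(default=0.025, ge=0.0, le=1.0)
    multi_episode_prob: float = Field(default=0.30, ge=0.0, le=1.0)
    n_units: int = Field(default=160, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "CohortConfig":
        unknown = set(self.condition_prevalences) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"condition_prevalences: unknown conditions {sorted(unknown)}")
        missing = set(CONDITIONS) - set(self.condition_prevalences)
        if missing:
            raise ValueError(f"condition_prevalences: missing conditions {sorted(missing)}")
        cpvl = self.condition_prevalences["cpvl"]
        if cpvl.term != 0.0:
            raise ValueError(
                "condition_prevalences[cpvl].term must be 0 (preterm-only condition)"
            )
        for stratum in ("term", "preterm"):
            p_s = getattr(self.condition_prevalences["seizures"], stratum)
            p_h = getattr(self.condition_prevalences["hie"], stratum)
            if self.seizure_given_hie * p_h > p_s + 1e-12:
                raise ValueError(
                    "seizure_given_hie * P(hie) exceeds the marginal seizure "
                    f"prevalence in the {stratum} stratum"
                )
        return self


@dataclass
class GroundTruth:
    """True per-infant flags and stratified counts for a synthetic cohort."""

    year: int
    infants: pd.DataFrame
    live_births: dict[str, int] = field(default_factory=dict)

    def counts(self) -> pd.DataFrame:
        """Tidy true counts: columns ``year, stratum, measure, count``.

        Composite measures count each infant once; per-condition measures
        count an infant once per condition held.
        """
        inf = self.infants
        ga = inf["gestational_weeks"]
        strata = {
            "all": pd.Series(True, index=inf.index),
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
                        "year": self.year,
                        "stratum": stratum,
                        "measure": m,
                        "count": int(inf.loc[mask, m].sum()),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.infants.to_csv(path, index=False)


def _sample_flags(
    rng: np.random.Generator, n: int, stratum: str, config: CohortConfig
) -> dict[str, np.ndarray]:
    """Independent Bernoulli flags, except seizures which co-occur with HIE."""
    prev = {c: getattr(config.condition_prevalences[c], stratum) for c in CONDITIONS}
    flags: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        if cond in ("seizures", "hie"):
            continue
        flags[cond] = rng.random(n) < prev[cond]
    hie = rng.random(n) < prev["hie"]
    flags["hie"] = hie
    # Seizures: P(seiz|HIE)=c, with the base rate solved so the marginal
    # stays at the configured prevalence: p = c*p_h + b*(1-p_h).
    c = config.seizure_given_hie
    p_s, p_h = prev["seizures"], prev["hie"]
    b = (p_s - c * p_h) / (1.0 - p_h) if p_h < 1.0 else p_s
    u = rng.random(n)
    flags["seizures"] = np.where(hie, u < c, u < b)
    return flags


def _assign_tokens(
    rng: np.random.Generator,
    flags: dict[str, np.ndarray],
    ga: np.ndarray,
    excl_token_idx: np.ndarray,
) -> tuple[list[list[str]], np.ndarray]:
    """Map true condition flags to raw diagnosis tokens per infant.

    Returns the per-infant token lists and the severe-P/IVH flag (grade 3-4
    haemorrhage token assigned, concentrated in the <32-week stratum).
    """
    n = len(ga)
    u_sev = rng.random(n)
    u_pick = rng.random(n)
    hie_sev = rng.choice(["HIE_MILD", "HIE_MOD", "HIE_SEV"], size=n, p=[0.3, 0.5, 0.2])
    ich = flags["intracranial_haemorrhage"]
    preterm = ga < TERM_WEEKS
    severe_p = np.where(ga < 32, 0.80, np.where(preterm, 0.25, 0.05))
    severe = ich & (u_sev < severe_p)
    tokens: list[list[str]] = []
    for i in range(n):
        toks: list[str] = []
        if flags["seizures"][i]:
            toks.append("SEIZ")
        if ich[i]:
            if severe[i]:
                toks.append("IVH_G3" if u_pick[i] < 0.5 else "IVH_G4")
            elif preterm[i]:
                toks.append("IVH_G1" if u_pick[i] < 0.5 else "IVH_G2")
            else:
                toks.append("ICH_OTHER")
        if flags["stroke"][i]:
            toks.append("STROKE")
        if flags["hie"][i]:
            toks.append(hie_sev[i])
        if flags["cns_infection"][i]:
            toks.append("CNS_INF")
        if flags["bilirubin_encephalopathy"][i]:
            toks.append("KERNICTERUS")
        if flags["cpvl"][i]:
            toks.append("CPVL")
        if excl_token_idx[i] >= 0:
            toks.append(_EXCLUSION_TOKENS[excl_token_idx[i]])
        tokens.append(toks)
    return tokens, severe


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one cohort year of episode records plus its ground truth.

    Deterministic given ``config.seed``. Every admitted infant has at least
    one episode carrying the full infant-level token set; infants drawn for
    a second episode get a later episode at the same unit with a random
    (possibly redundant, possibly empty) subset of their tokens.
    """
    config = CohortConfig.model_validate(config)
    rng = np.random.default_rng(config.seed)
    n_preterm_births = int(rng.binomial(config.n_live_births, config.preterm_fraction))
    n_term_births = config.n_live_births - n_preterm_births
    n_adm_term = int(rng.binomial(n_term_births, config.admission_prob_term))
    n_adm_pre = int(rng.binomial(n_preterm_births, config.admission_prob_preterm))

    ga = np.concatenate(
        [
            rng.integers(37, 42, size=n_adm_term),
            rng.choice(_PRETERM_WEEKS, size=n_adm_pre, p=_PRETERM_WEIGHTS),
        ]
    ).astype(np.int64)
    n = n_adm_term + n_adm_pre

    flags_t = _sample_flags(rng, n_adm_term, "term", config)
    flags_p = _sample_flags(rng, n_adm_pre, "preterm", config)
    flags = {c: np.concatenate([flags_t[c], flags_p[c]]) for c in CONDITIONS}

    # Congenital-exclusion diagnoses on a fraction of seizure cases.
    excl_idx = np.full(n, -1, dtype=np.int64)
    seiz = flags["seizures"]
    has_excl = seiz & (rng.random(n) < config.exclusion_prob_given_seizure)
    excl_idx[has_excl] = rng.integers(0, len(_EXCLUSION_TOKENS), size=int(has_excl.sum()))

    tokens, severe = _assign_tokens(rng, flags, ga, excl_idx)

    unit = rng.integers(0, config.n_units, size=n)
    unit_ids = np.array([f"U{u:03d}" for u in unit])
    infant_ids = np.array([f"{config.year}-{i:06d}" for i in range(n)])

    base = np.datetime64(f"{config.year}-01-01")
    adm_off = rng.integers(0, 365, size=n)
    los_term = rng.integers(1, 15, size=n)
    los_pre = np.maximum(2, ((40 - ga) * 5 + rng.integers(0, 11, size=n) - 5))
    los = np.where(ga < TERM_WEEKS, los_pre, los_term)
    adm1 = base + adm_off
    dis1 = adm1 + los

    multi = rng.random(n) < config.multi_episode_prob
    gap = rng.integers(1, 8, size=n)
    los2 = rng.integers(1, 15, size=n)
    adm2 = dis1 + gap
    dis2 = adm2 + los2

    rows: list[tuple] = []
    for i in range(n):
        codes1 = format_codes(tokens[i])
        rows.append(
            (
                infant_ids[i],
                unit_ids[i],
                config.year,
                str(adm1[i]),
                str(dis1[i]),
                int(ga[i]),
                codes1,
            )
        )
        if multi[i]:
            toks_i = sorted(tokens[i])
            keep = rng.random(len(toks_i)) < 0.5
            sub = [t for t, k in zip(toks_i, keep) if k]
            rows.append(
                (
                    infant_ids[i],
                    unit_ids[i],
                    config.year,
                    str(adm2[i]),
                    str(dis2[i]),
                    int(ga[i]),
                    format_codes(sub),
                )
            )
    episodes = pd.DataFrame(rows, columns=list(EPISODE_COLUMNS))

    other = [c for c in CONDITIONS if c != "seizures"]
    any_other = np.logical_or.reduce([flags[c] for c in other])
    composite_before = seiz | any_other
    excluded = seiz & ~any_other & (excl_idx >= 0)
    composite_after = composite_before & ~excluded

    infants = pd.DataFrame(
        {
            "infant_id": infant_ids,
            "unit_id": unit_ids,
            "gestational_weeks": ga,
            "stratum": np.where(ga >= TERM_WEEKS, "term", "preterm"),
            "n_episodes": np.where(multi, 2, 1),
            **{c: flags[c] for c in CONDITIONS},
            "severe_pivh": severe,
            "has_exclusion_code": excl_idx >= 0,
            "excluded": excluded,
            "composite_before": composite_before,
            "composite_after": composite_after,
        }
    )
    truth = GroundTruth(
        year=config.year,
        infants=infants,
        live_births={
            "all": config.n_live_births,
            "term": n_term_births,
            "preterm": n_preterm_births,
        },
    )
    return episodes, truth


def apply_coverage_mask(
    records: pd.DataFrame, participating_units: set[str]
) -> pd.DataFrame:
    """Keep only episodes from participating units (no record mutated).

    Models registry years when a fraction of units did not contribute data:
    an infant whose episodes all fall in non-participating units disappears
    from the observable cohort.
    """
    if not participating_units:
        raise ValueError("participating_units is empty: no observable cohort")
    mask = records["unit_id"].isin(participating_units)
    return records.loc[mask].reset_index(drop=True)


def inject_dirty_records(
    records: pd.DataFrame,
    dup_rate: float,
    out_of_range_rate: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Append exact-duplicate and impossible-value episodes at stated rates.

    Corrupt rows are *copies* of clean episodes (gestational age 99 weeks, or
    discharge before admission), so the clean cohort remains fully present
    and the injected rows form an exact oracle for the cleaning stage.

    Returns ``(dirty, sidecar)`` where ``sidecar`` lists the injected rows
    with a ``kind`` column in {duplicate, gestation_out_of_range,
    date_interval_inverted}.
    """
    if not 0.0 <= dup_rate <= 1.0 or not 0.0 <= out_of_range_rate <= 1.0:
        raise ValueError("dup_rate and out_of_range_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(records)
    injected: list[pd.DataFrame] = []
    kinds: list[np.ndarray] = []

    dup_mask = rng.random(n) < dup_rate
    if dup_mask.any():
        dups = records.loc[dup_mask].copy()
        injected.append(dups)
        kinds.append(np.repeat("duplicate", len(dups)))

    oor_mask = rng.random(n) < out_of_range_rate
    if oor_mask.any():
        bad = records.loc[oor_mask].copy()
        which = rng.random(len(bad)) < 0.5
        bad_kinds = np.where(which, "gestation_out_of_range", "date_interval_inverted")
        bad.loc[which, "gestational_weeks"] = 99
        inv = ~which
        if inv.any():
            adm = bad.loc[inv, "admission_date"].copy()
            bad.loc[inv, "admission_date"] = bad.loc[inv, "discharge_date"].values
            bad.loc[inv, "discharge_date"] = adm.values
        injected.append(bad)
        kinds.append(bad_kinds)

    if not injected:
        return records.copy().reset_index(drop=True), pd.DataFrame(
            columns=list(EPISODE_COLUMNS) + ["kind"]
        )

    extra = pd.concat(injected, ignore_index=True)
    sidecar = extra.copy()
    sidecar["kind"] = np.concatenate(kinds)
    dirty = pd.concat([records, extra], ignore_index=True)
    order = rng.permutation(len(dirty))
    dirty = dirty.iloc[order].reset_index(drop=True)
    return dirty, sidecar.reset_index(drop=True)
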