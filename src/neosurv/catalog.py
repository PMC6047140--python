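"""Condition catalog: mapping from raw diagnosis tokens to surveillance conditions.

The composite case definition covers seven conditions detected during the
neonatal-unit stay — seizures, intracranial haemorrhage, perinatal/neonatal
stroke, hypoxic-ischaemic encephalopathy (HIE), central nervous system
infection, bilirubin encephalopathy (kernicterus) and, in preterm infants
only, cystic periventricular leucomalacia (cPVL) — together with a set of
exclusion diagnoses indicating that a brain injury was of antenatal origin
(congenital encephalopathies including inborn errors of metabolism,
congenital infections, congenital brain abnormalities).

The catalog shipped here is a configurable stand-in: real registries carry
their own controlled code lists, so every token set can be replaced from a
YAML file without touching the classification logic.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, field_validator, model_validator

#: Canonical condition names, in reporting order.
CONDITIONS: tuple[str, ...] = (
    "seizures",
    "intracranial_haemorrhage",
    "stroke",
    "hie",
    "cns_infection",
    "bilirubin_encephalopathy",
    "cpvl",
)

#: Strata used throughout counting and rate estimation.
STRATA: tuple[str, ...] = ("all", "term", "preterm", "lt32", "lt34", "missing_ga")

TERM_WEEKS = 37  # term = gestational age >= 37 completed weeks


class ConditionDef(BaseModel):
    """One target condition: its tokens and optional population restriction."""

    tokens: frozenset[str]
    restriction: Optional[Literal["preterm_only"]] = None
    #: subset of ``tokens`` flagged as severe (e.g. grade 3-4 P/IVH)
    severe_tokens: frozenset[str] = frozenset()

    @model_validator(mode="after")
    def _severe_subset(self) -> "ConditionDef":
        if not self.severe_tokens <= self.tokens:
            raise ValueError("severe_tokens must be a subset of tokens")
        return self


class ConditionCatalog(BaseModel):
    """Token sets for the seven inclusion conditions and the exclusion groups.

    Invariants: inclusion and exclusion token sets are pairwise disjoint, and
    cPVL is restricted to preterm infants (gestational age < 37 weeks).
    """

    conditions: dict[str, ConditionDef]
    exclusions: dict[str, frozenset[str]]

    @field_validator("conditions")
    @classmethod
    def _known_conditions(cls, v: dict[str, ConditionDef]) -> dict[str, ConditionDef]:
        unknown = set(v) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition names: {sorted(unknown)}")
        return v

    @model_validator(mode="after")
    def _disjoint_and_restricted(self) -> "ConditionCatalog":
        incl = self.inclusion_tokens
        excl = self.exclusion_tokens
        overlap = incl & excl
        if overlap:
            raise ValueError(
                f"tokens shared between inclusion and exclusion sets: {sorted(overlap)}"
            )
        cpvl = self.conditions.get("cpvl")
        if cpvl is not None and cpvl.restriction != "preterm_only":
            raise ValueError("cpvl must carry the preterm_only restriction")
        return self

    @property
    def inclusion_tokens(self) -> frozenset[str]:
        out: set[str] = set()
        for cdef in self.conditions.values():
            out |= cdef.tokens
        return frozenset(out)

    @property
    def exclusion_tokens(self) -> frozenset[str]:
        out: set[str] = set()
        for toks in self.exclusions.values():
            out |= toks
        return frozenset(out)

    @property
    def known_tokens(self) -> frozenset[str]:
        return self.inclusion_tokens | self.exclusion_tokens

    # -- serialisation ------------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = {
            "conditions": {
                name: {
                    "tokens": sorted(cdef.tokens),
                    **({"restriction": cdef.restriction} if cdef.restriction else {}),
                    **(
                        {"severe_tokens": sorted(cdef.severe_tokens)}
                        if cdef.severe_tokens
                        else {}
                    ),
                }
                for name, cdef in self.conditions.items()
            },
            "exclusions": {k: sorted(v) for k, v in self.exclusions.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ConditionCatalog":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls.model_validate(payload)


def default_catalog() -> ConditionCatalog:
    """Stand-in token catalog at the granularity the surveillance needs.

    Intracranial haemorrhage carries a severe subset (grade 3-4
    intraventricular/periventricular haemorrhage); HIE tokens are graded so a
    catalog edit can restrict ascertainment to moderate/severe disease.
    """
    return ConditionCatalog(
        conditions={
            "seizures": ConditionDef(tokens=frozenset({"SEIZ"})),
            "intracranial_haemorrhage": ConditionDef(
                tokens=frozenset(
                    {"IVH_G1", "IVH_G2", "IVH_G3", "IVH_G4", "ICH_OTHER"}
                ),
                severe_tokens=frozenset({"IVH_G3", "IVH_G4"}),
            ),
            "stroke": ConditionDef(tokens=frozenset({"STROKE"})),
            "hie": ConditionDef(tokens=frozenset({"HIE_MILD", "HIE_MOD", "HIE_SEV"})),
            "cns_infection": ConditionDef(tokens=frozenset({"CNS_INF"})),
            "bilirubin_encephalopathy": ConditionDef(
                tokens=frozenset({"KERNICTERUS"})
            ),
            "cpvl": ConditionDef(
                tokens=frozenset({"CPVL"}), restriction="preterm_only"
            ),
        },
        exclusions={
            "congenital_encephalopathy": frozenset({"CONG_ENCEPH", "IEM"}),
            "congenital_infection": frozenset({"CONG_INF"}),
            "congenital_brain_abnormality": frozenset({"CONG_BRAIN_ABN"}),
        },
    )


def parse_codes(codes: object) -> frozenset[str]:
    """Parse the semicolon-separated ``codes`` CSV field into a token set."""
    if codes is None or codes != codes:  # NaN
        return frozenset()
    s = str(codes).strip()
    if not s:
        return frozenset()
    return frozenset(tok for tok in s.split(";") if tok)


def format_codes(tokens) -> str:
    """Inverse of :func:`parse_codes`; deterministic (sorted) rendering."""
    return ";".join(sorted(tokens))
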