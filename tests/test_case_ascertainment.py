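"""Composite case definition: flags, exclusion rule, stratified counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neosurv import (
    CONDITIONS,
    classify_cohort,
    classify_infant,
    count_cases,
    default_catalog,
)
from neosurv.catalog import ConditionCatalog, ConditionDef

CATALOG = default_catalog()
TOKEN_UNIVERSE = sorted(CATALOG.known_tokens) + ["JUNK1", "ZZZ"]


def brute_force_classify(codes: set, ga, catalog: ConditionCatalog):
    """Independent oracle: enumerate every condition by set intersection."""
    flags = {}
    for cond, cdef in catalog.conditions.items():
        hit = any(tok in cdef.tokens for tok in codes)
        if cdef.restriction == "preterm_only":
            hit = hit and ga is not None and ga == ga and ga < 37
        flags[cond] = hit
    composite = any(flags.values())
    seizure_only = flags["seizures"] and not any(
        flags[c] for c in flags if c != "seizures"
    )
    excl = any(tok in catalog.exclusion_tokens for tok in codes)
    excluded = composite and seizure_only and excl
    return flags, composite, composite and not excluded


def make_infant(codes, ga, infant_id="X"):
    return {
        "infant_id": infant_id,
        "codes": ";".join(sorted(codes)),
        "gestational_weeks": ga,
    }


class TestClassifyInfant:
    def test_term_infant_with_cpvl_token_is_not_a_case(self):
        res = classify_infant(make_infant({"CPVL"}, 40), CATALOG)
        assert not any(res.flags.values())
        assert not res.composite_before_exclusions

    def test_preterm_infant_with_cpvl_token_is_a_case(self):
        res = classify_infant(make_infant({"CPVL"}, 30), CATALOG)
        assert res.flags["cpvl"]
        assert res.composite_before_exclusions

    def test_empty_codes_not_a_case(self):
        res = classify_infant(make_infant(set(), 40), CATALOG)
        assert not res.composite_before_exclusions

    def test_unknown_token_warned_not_fatal(self, caplog):
        with caplog.at_level("WARNING"):
            res = classify_infant(make_infant({"NOT_A_CODE", "SEIZ"}, 40), CATALOG)
        assert res.flags["seizures"]
        assert any("NOT_A_CODE" in m for m in caplog.messages)

    @settings(derandomize=True, max_examples=200)
    @given(
        codes=st.sets(st.sampled_from(TOKEN_UNIVERSE), max_size=3),
        ga=st.one_of(st.none(), st.integers(min_value=22, max_value=44)),
    )
    def test_matches_brute_force_oracle(self, codes, ga):
        flags, before, after = brute_force_classify(codes, ga, CATALOG)
        res = classify_infant(make_infant(codes, np.nan if ga is None else ga), CATALOG)
        assert res.flags == flags
        assert res.composite_before_exclusions == before
        assert res.composite_after_exclusions == after

    @settings(derandomize=True, max_examples=50)
    @given(
        cohort=st.lists(
            st.tuples(
                st.sets(st.sampled_from(TOKEN_UNIVERSE), max_size=3),
                st.integers(min_value=22, max_value=44),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_cohort_classifier_matches_per_infant_oracle(self, cohort):
        infants = pd.DataFrame(
            [make_infant(c, ga, infant_id=f"I{i}") for i, (c, ga) in enumerate(cohort)]
        )
        res = classify_cohort(infants, CATALOG)
        for i, (codes, ga) in enumerate(cohort):
            flags, before, after = brute_force_classify(codes, ga, CATALOG)
            row = res.iloc[i]
            assert {c: bool(row[c]) for c in CONDITIONS} == flags
            assert bool(row["composite_before"]) == before
            assert bool(row["composite_after"]) == after


class TestExclusionRule:
    def test_seizure_only_with_congenital_token_excluded(self):
        res = classify_infant(make_infant({"SEIZ", "CONG_INF"}, 40), CATALOG)
        assert res.composite_before_exclusions
        assert res.excluded
        assert not res.composite_after_exclusions

    def test_seizure_plus_hie_with_congenital_token_retained(self):
        res = classify_infant(make_infant({"SEIZ", "HIE_MOD", "CONG_INF"}, 40), CATALOG)
        assert res.composite_after_exclusions
        assert not res.excluded

    def test_non_seizure_case_with_congenital_token_retained(self):
        res = classify_infant(make_infant({"STROKE", "CONG_ENCEPH"}, 40), CATALOG)
        assert res.composite_after_exclusions

    def test_no_exclusion_tokens_before_equals_after(self, small_cohort):
        _, _, truth = small_cohort
        infants = pd.DataFrame(
            {
                "infant_id": ["A", "B"],
                "codes": ["SEIZ", "IVH_G3"],
                "gestational_weeks": [40, 28],
            }
        )
        res = classify_cohort(infants, CATALOG)
        assert (res["composite_before"] == res["composite_after"]).all()

    def test_after_exclusions_never_exceeds_before(self, small_cohort):
        _, episodes, _ = small_cohort
        from neosurv import clean_episodes, merge_to_infants

        infants, _ = merge_to_infants(clean_episodes(episodes)[0])
        res = classify_cohort(infants, CATALOG)
        assert res["composite_after"].sum() <= res["composite_before"].sum()
        assert (res["composite_after"] <= res["composite_before"]).all()


class TestCountCases:
    @pytest.fixture()
    def counted(self, small_cohort):
        from neosurv import clean_episodes, merge_to_infants

        _, episodes, truth = small_cohort
        infants, _ = merge_to_infants(clean_episodes(episodes)[0])
        res = classify_cohort(infants, CATALOG)
        return count_cases(res, infants, year=2015), truth

    def test_counts_equal_ground_truth_exactly(self, counted):
        counts, truth = counted
        merged = counts.merge(
            truth.counts(), on=["year", "stratum", "measure"], suffixes=("", "_true")
        )
        assert (merged["count"] == merged["count_true"]).all()

    def test_composite_counted_once_inequality(self, counted):
        counts, _ = counted
        idx = counts.set_index(["stratum", "measure"])["count"]
        per_condition = sum(idx.loc[("all", c)] for c in CONDITIONS)
        assert idx.loc[("all", "composite_before")] <= per_condition

    def test_term_preterm_missing_partition(self, counted):
        counts, _ = counted
        idx = counts.set_index(["stratum", "measure"])["count"]
        for measure in ("composite_after", "seizures", "hie"):
            assert (
                idx.loc[("term", measure)]
                + idx.loc[("preterm", measure)]
                + idx.loc[("missing_ga", measure)]
                == idx.loc[("all", measure)]
            )

    def test_missing_ga_counted_in_all_but_not_ga_strata(self):
        infants = pd.DataFrame(
            {
                "infant_id": ["A"],
                "codes": ["SEIZ"],
                "gestational_weeks": [np.nan],
            }
        )
        res = classify_cohort(infants, CATALOG)
        counts = count_cases(res, infants, year=2015)
        idx = counts.set_index(["stratum", "measure"])["count"]
        assert idx.loc[("all", "seizures")] == 1
        assert idx.loc[("missing_ga", "seizures")] == 1
        assert idx.loc[("term", "seizures")] == 0
        assert idx.loc[("preterm", "seizures")] == 0


class TestCatalogModularity:
    def test_removing_a_token_set_zeroes_only_that_condition(self, small_cohort):
        from neosurv import clean_episodes, merge_to_infants

        _, episodes, _ = small_cohort
        infants, _ = merge_to_infants(clean_episodes(episodes)[0])
        stripped = ConditionCatalog(
            conditions={
                **CATALOG.conditions,
                "stroke": ConditionDef(tokens=frozenset({"UNUSED_TOKEN"})),
            },
            exclusions=CATALOG.exclusions,
        )
        base = classify_cohort(infants, CATALOG)
        out = classify_cohort(infants, stripped)
        assert out["stroke"].sum() == 0
        for cond in CONDITIONS:
            if cond != "stroke":
                assert out[cond].equals(base[cond])

    def test_inclusion_exclusion_token_overlap_rejected(self):
        with pytest.raises(Exception, match="shared"):
            ConditionCatalog(
                conditions={
                    "seizures": ConditionDef(tokens=frozenset({"SEIZ", "CONG_INF"})),
                    "cpvl": ConditionDef(
                        tokens=frozenset({"CPVL"}), restriction="preterm_only"
                    ),
                },
                exclusions={"congenital_infection": frozenset({"CONG_INF"})},
            )

    def test_catalog_yaml_round_trip(self, tmp_path):
        path = tmp_path / "catalog.yaml"
        CATALOG.to_yaml(path)
        assert ConditionCatalog.from_yaml(path) == CATALOG
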