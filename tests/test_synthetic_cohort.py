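"""Generator: determinism, ground-truth consistency, masking, dirty records."""

import math

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from neosurv import (
    CohortConfig,
    apply_coverage_mask,
    generate_cohort,
    inject_dirty_records,
)
from neosurv.synthetic_cohort import EPISODE_COLUMNS, StratumPrevalence


def zero_prevalence_config(**kw):
    prevs = {
        c: StratumPrevalence(term=0.0, preterm=0.0)
        for c in CohortConfig().condition_prevalences
    }
    return CohortConfig(
        n_live_births=5_000, condition_prevalences=prevs, seed=3, **kw
    )


class TestConfigValidation:
    def test_term_cpvl_must_be_zero(self):
        cfg = CohortConfig()
        prevs = dict(cfg.condition_prevalences)
        prevs["cpvl"] = StratumPrevalence(term=0.01, preterm=0.01)
        with pytest.raises(ValidationError, match="cpvl"):
            CohortConfig(condition_prevalences=prevs)

    def test_probabilities_bounded(self):
        with pytest.raises(ValidationError, match="admission_prob_term"):
            CohortConfig(admission_prob_term=1.5)

    def test_positive_birth_count(self):
        with pytest.raises(ValidationError, match="n_live_births"):
            CohortConfig(n_live_births=0)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        cfg = CohortConfig(n_live_births=8_000, seed=11)
        e1, t1 = generate_cohort(cfg)
        e2, t2 = generate_cohort(cfg)
        assert e1.equals(e2)
        assert t1.infants.equals(t2.infants)
        assert e1.to_csv(index=False) == e2.to_csv(index=False)

    def test_different_seeds_differ(self):
        e1, _ = generate_cohort(CohortConfig(n_live_births=8_000, seed=1))
        e2, _ = generate_cohort(CohortConfig(n_live_births=8_000, seed=2))
        assert not e1.equals(e2)

    def test_zero_prevalence_cohort_has_no_cases(self):
        _, truth = generate_cohort(zero_prevalence_config())
        assert truth.infants["composite_before"].sum() == 0
        counts = truth.counts()
        assert (
            counts.loc[counts["measure"] == "composite_before", "count"] == 0
        ).all()

    def test_every_infant_has_an_episode_and_consistent_fields(self, small_cohort):
        _, episodes, truth = small_cohort
        per_infant = episodes.groupby("infant_id")
        assert set(episodes["infant_id"]) == set(truth.infants["infant_id"])
        assert (per_infant.size() >= 1).all()
        # infant-level fields consistent across a multi-episode infant
        assert (per_infant["gestational_weeks"].nunique() == 1).all()
        assert (per_infant["unit_id"].nunique() == 1).all()

    def test_multi_episode_infants_have_two_episodes(self, small_cohort):
        _, episodes, truth = small_cohort
        sizes = episodes.groupby("infant_id").size()
        expected = truth.infants.set_index("infant_id")["n_episodes"]
        assert sizes.sort_index().equals(expected.sort_index())
        assert (sizes == 2).sum() > 0

    def test_cpvl_never_generated_for_term_infants(self):
        # lift preterm cpvl prevalence so the check has power
        cfg = CohortConfig(n_live_births=30_000, seed=5)
        prevs = dict(cfg.condition_prevalences)
        prevs["cpvl"] = StratumPrevalence(term=0.0, preterm=0.2)
        cfg = cfg.model_copy(update={"condition_prevalences": prevs})
        _, truth = generate_cohort(cfg)
        term = truth.infants[truth.infants["stratum"] == "term"]
        assert truth.infants["cpvl"].sum() > 0
        assert term["cpvl"].sum() == 0

    def test_seizure_count_within_three_binomial_sd(self):
        # binomial expectation computed analytically from the config
        cfg = CohortConfig(
            n_live_births=10_000,
            preterm_fraction=0.07,
            seed=17,
            condition_prevalences={
                **CohortConfig().condition_prevalences,
                "seizures": StratumPrevalence(term=0.02, preterm=0.02),
                "hie": StratumPrevalence(term=0.0, preterm=0.0),
            },
        )
        _, truth = generate_cohort(cfg)
        q = (
            0.07 * cfg.admission_prob_preterm + 0.93 * cfg.admission_prob_term
        ) * 0.02  # P(live birth is admitted and has seizures)
        expected = cfg.n_live_births * q
        sd = math.sqrt(cfg.n_live_births * q * (1 - q))
        assert abs(truth.infants["seizures"].sum() - expected) <= 3 * sd

    def test_seizure_marginal_preserved_under_hie_cooccurrence(self):
        # P(seizures) stays at the configured value; P(seizures | HIE) rises
        cfg = CohortConfig(n_live_births=150_000, seed=23, seizure_given_hie=0.25)
        _, truth = generate_cohort(cfg)
        term = truth.infants[truth.infants["stratum"] == "term"]
        p = term["seizures"].mean()
        p_cfg = cfg.condition_prevalences["seizures"].term
        sd = math.sqrt(p_cfg * (1 - p_cfg) / len(term))
        assert abs(p - p_cfg) <= 4 * sd
        p_given_hie = term.loc[term["hie"], "seizures"].mean()
        assert p_given_hie > 3 * p

    def test_composite_counted_once_in_ground_truth(self, small_cohort):
        _, _, truth = small_cohort
        inf = truth.infants
        from neosurv import CONDITIONS

        any_flag = inf[list(CONDITIONS)].any(axis=1)
        assert (inf["composite_before"] == any_flag).all()
        assert inf["composite_after"].sum() <= inf["composite_before"].sum()


class TestCoverageMask:
    def test_all_units_participating_is_identity(self, small_cohort):
        _, episodes, _ = small_cohort
        out = apply_coverage_mask(episodes, set(episodes["unit_id"].unique()))
        assert out.reset_index(drop=True).equals(episodes.reset_index(drop=True))

    def test_empty_participating_set_raises(self, small_cohort):
        _, episodes, _ = small_cohort
        with pytest.raises(ValueError, match="empty"):
            apply_coverage_mask(episodes, set())

    def test_masked_infants_absent(self, small_cohort):
        _, episodes, _ = small_cohort
        units = sorted(episodes["unit_id"].unique())
        dropped = {units[0]}
        out = apply_coverage_mask(episodes, set(units) - dropped)
        gone = set(episodes.loc[episodes["unit_id"].isin(dropped), "infant_id"])
        assert gone and not (set(out["infant_id"]) & gone)

    def test_ninety_percent_units_keeps_ninety_percent_admissions(self):
        cfg = CohortConfig(n_live_births=60_000, n_units=10, seed=31)
        episodes, truth = generate_cohort(cfg)
        units = sorted(episodes["unit_id"].unique())
        out = apply_coverage_mask(episodes, set(units[:9]))
        n = len(truth.infants)
        kept_infants = out["infant_id"].nunique()
        sd = math.sqrt(n * 0.9 * 0.1)
        assert abs(kept_infants - 0.9 * n) <= 3 * sd


class TestInjectDirtyRecords:
    def test_zero_rates_identity(self, small_cohort):
        _, episodes, _ = small_cohort
        dirty, sidecar = inject_dirty_records(episodes, 0.0, 0.0, seed=1)
        assert dirty.equals(episodes.reset_index(drop=True))
        assert sidecar.empty

    def test_dup_rate_one_duplicates_every_episode(self, small_cohort):
        _, episodes, _ = small_cohort
        dirty, sidecar = inject_dirty_records(episodes, 1.0, 0.0, seed=1)
        sizes = dirty.groupby(list(EPISODE_COLUMNS)).size()
        assert (sizes >= 2).all()
        assert len(sidecar) == len(episodes)
        assert (sidecar["kind"] == "duplicate").all()

    def test_out_of_range_count_within_three_binomial_sd(self, small_cohort):
        _, episodes, _ = small_cohort
        rate = 0.05
        _, sidecar = inject_dirty_records(episodes, 0.0, rate, seed=9)
        n = len(episodes)
        sd = math.sqrt(n * rate * (1 - rate))
        assert abs(len(sidecar) - n * rate) <= 3 * sd
        assert set(sidecar["kind"]) <= {
            "gestation_out_of_range",
            "date_interval_inverted",
        }

    def test_invalid_rates_rejected(self, small_cohort):
        _, episodes, _ = small_cohort
        with pytest.raises(ValueError):
            inject_dirty_records(episodes, -0.1, 0.0, seed=1)
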