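"""Synthetic cohort generator: margins, correlations, oversampling,
missingness and determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import persrisk as pr
from persrisk.simulate import TABLE_PREVALENCES, phi_coefficient


def _plain_spec(**kwargs) -> pr.CohortSpec:
    """No oversampling, no missingness: the raw population margins."""
    base = dict(missingness={}, outcome_missingness={}, oversampling=None)
    base.update(kwargs)
    return pr.CohortSpec(**base)


class TestDeterminism:
    def test_same_seed_identical_cohort(self):
        spec = pr.CohortSpec(n_subjects=500, seed=7)
        a = pr.generate_cohort(spec)
        b = pr.generate_cohort(spec)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_different_seed_differs(self):
        a = pr.generate_cohort(pr.CohortSpec(n_subjects=500, seed=7))
        b = pr.generate_cohort(pr.CohortSpec(n_subjects=500, seed=8))
        assert not a.equals(b)


class TestMargins:
    def test_urban_prevalence_matches_study_margin(self):
        cohort = pr.generate_cohort(_plain_spec(n_subjects=10000, seed=1))
        urban = pr.binarize(cohort)["urban"].mean()
        assert urban == pytest.approx(0.787, abs=0.013)

    def test_all_margins_within_binomial_tolerance(self):
        n = 20000
        cohort = pr.generate_cohort(_plain_spec(n_subjects=n, seed=2))
        prof = pr.binarize(cohort)
        for factor, p in TABLE_PREVALENCES.items():
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(prof[factor].mean() - p) < 4 * sd, factor

    def test_strong_perinatal_pair_correlation(self):
        cohort = pr.generate_cohort(_plain_spec(n_subjects=20000, seed=3))
        prof = pr.binarize(cohort)
        phi = phi_coefficient(prof["low_gestational_age"], prof["low_birth_weight"])
        assert phi == pytest.approx(0.57, abs=0.03)

    def test_infeasible_correlation_rejected_naming_pair(self):
        spec = _plain_spec(
            n_subjects=100,
            correlation_pairs=(("cannabis", "urban", 0.9),),
        )
        with pytest.raises(pr.InfeasibleCorrelationError, match="0.9"):
            pr.generate_cohort(spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            pr.CohortSpec(n_subjects=0).validate()
        with pytest.raises(ValueError):
            pr.CohortSpec(factor_prevalences={**TABLE_PREVALENCES, "urban": 1.5}).validate()


class TestOutcomeModel:
    def test_null_effect_outcome_independent_of_score(self):
        spec = _plain_spec(
            n_subjects=20000,
            seed=4,
            outcome_model=pr.OutcomeModel(intercept=-1.0, beta_per_unit_score=0.0),
        )
        cohort = pr.generate_cohort(spec)
        scores = pr.score_cohort(pr.binarize(cohort), schemes=("updated_pers",))
        r = np.corrcoef(scores["pers_scaled"], cohort["ps_flag"])[0, 1]
        assert abs(r) < 0.02
        expected = 1.0 / (1.0 + np.exp(1.0))
        assert cohort["ps_flag"].mean() == pytest.approx(expected, abs=0.02)

    def test_calibration_hits_target_combined_prevalence(self):
        spec = _plain_spec(n_subjects=10000)
        intercept = pr.calibrate_intercept(spec, target_prevalence=0.215, n_sim=20000, seed=5)
        tuned = dataclasses.replace(
            spec, outcome_model=pr.OutcomeModel(intercept=intercept), seed=6
        )
        cohort = pr.generate_cohort(tuned)
        out = pr.derive_outcomes(cohort["pq16_total"], cohort["ps_flag"])
        assert out["pe_or_ps"].mean() == pytest.approx(0.215, abs=0.015)


class TestMissingness:
    def test_zero_rates_leave_cohort_unchanged(self, complete_cohort):
        rates = {"paternal_age_at_birth": 0.0, "birth_weight": 0.0}
        out = pr.inject_missingness(complete_cohort, rates, seed=0)
        pd.testing.assert_frame_equal(out, complete_cohort)

    def test_thirty_percent_paternal_age(self):
        cohort = pr.generate_cohort(_plain_spec(n_subjects=10000, seed=7))
        out = pr.inject_missingness(cohort, {"paternal_age_at_birth": 0.30}, seed=1)
        n_missing = out["paternal_age_at_birth"].isna().sum()
        sd = np.sqrt(0.3 * 0.7 * 10000)
        assert abs(n_missing - 3000) < 4 * sd

    def test_bullying_count_at_study_scale(self):
        cohort = pr.generate_cohort(_plain_spec(n_subjects=801, seed=8))
        out = pr.inject_missingness(cohort, {"bullying": 72 / 801}, seed=2)
        n_missing = out["bullied_multiple"].isna().sum()
        sd = np.sqrt((72 / 801) * (1 - 72 / 801) * 801)
        assert abs(n_missing - 72) < 4 * sd

    def test_unknown_variable_rejected(self, complete_cohort):
        with pytest.raises(ValueError, match="unknown variable"):
            pr.inject_missingness(complete_cohort, {"nonexistent": 0.1}, seed=0)

    def test_outcomes_never_masked_by_default(self, complete_cohort):
        with pytest.raises(ValueError, match="never masked"):
            pr.inject_missingness(complete_cohort, {"ps_flag": 0.1}, seed=0)

    def test_mar_mechanism_preserves_overall_rate(self, complete_cohort):
        out = pr.inject_missingness(
            complete_cohort, {"paternal_age_at_birth": 0.3}, seed=3, mar_strength=0.7
        )
        frac = out["paternal_age_at_birth"].isna().mean()
        assert frac == pytest.approx(0.3, abs=0.05)
        # missingness depends on the observed covariate under MAR
        miss = out["paternal_age_at_birth"].isna()
        assert (
            out.loc[miss, "age_baseline"].mean()
            > out.loc[~miss, "age_baseline"].mean()
        )


class TestOversampling:
    @staticmethod
    def _population(n=20000, seed=9):
        return pr.generate_population(
            _plain_spec(), n, np.random.default_rng(seed)
        )

    def test_ratio_one_is_simple_random_sample(self):
        pop = self._population()
        cohort = pr.apply_oversampling(pop, 0.15, 1.0, 5000, seed=1)
        cutoff = pop["screening_score"].quantile(0.85)
        share = (cohort["screening_score"] > cutoff).mean()
        assert share == pytest.approx(0.15, abs=0.02)

    def test_high_scorer_share_matches_closed_form(self):
        # expected share = .15*2.5 / (.15*2.5 + .85) = 0.306
        pop = self._population(n=40000)
        cohort = pr.apply_oversampling(pop, 0.15, 2.5, 8000, seed=2)
        cutoff = pop["screening_score"].quantile(0.85)
        share = (cohort["screening_score"] > cutoff).mean()
        expected = 0.15 * 2.5 / (0.15 * 2.5 + 0.85)
        sd = np.sqrt(expected * (1 - expected) / 8000)
        assert abs(share - expected) < 4 * sd

    def test_requested_size_exceeding_population_rejected(self):
        pop = self._population(n=1000)
        with pytest.raises(ValueError, match="exceeds population"):
            pr.apply_oversampling(pop, 0.15, 2.5, 2000, seed=0)

    def test_screening_enriches_adversity(self):
        """Oversampling on the screening score raises adversity prevalence
        relative to the source population (latent correlation 0.3)."""
        pop = self._population(n=40000)
        cohort = pr.apply_oversampling(pop, 0.15, 2.5, 8000, seed=3)
        assert (
            pr.binarize(cohort)["emotional_abuse"].mean()
            > pr.binarize(pop)["emotional_abuse"].mean()
        )
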