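"""Regression layer: logistic oracle equivalence, bands, BH, Nagelkerke and
scheme comparison."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import persrisk as pr


def _two_by_two(a, b, c, d) -> pd.DataFrame:
    """exposed: a cases / b non-cases; unexposed: c cases / d non-cases."""
    return pd.DataFrame(
        {
            "exposure": [1.0] * (a + b) + [0.0] * (c + d),
            "y": [1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d,
        }
    )


class TestLogistic:
    def test_two_by_two_matches_cross_product_ratio(self):
        fit = pr.fit_logistic(_two_by_two(20, 30, 10, 40), "y", ["exposure"], covariates=())
        assert math.exp(fit.params["exposure"]) == pytest.approx(
            (20 * 40) / (30 * 10), rel=1e-6
        )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.tuples(*[st.integers(3, 60)] * 4))
    def test_cross_product_oracle_property(self, cells):
        a, b, c, d = cells
        fit = pr.fit_logistic(_two_by_two(a, b, c, d), "y", ["exposure"], covariates=())
        assert math.exp(fit.params["exposure"]) == pytest.approx(
            (a * d) / (b * c), rel=1e-6
        )

    def test_null_exposure_gives_or_near_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"exposure": rng.integers(0, 2, 20000).astype(float),
             "y": (rng.random(20000) < 0.2).astype(float)}
        )
        fit = pr.fit_logistic(df, "y", ["exposure"], covariates=())
        assert abs(fit.params["exposure"]) < 3 * fit.bse["exposure"]

    def test_single_class_outcome_rejected(self):
        df = _two_by_two(0, 30, 0, 40)
        with pytest.raises(ValueError, match="single class"):
            pr.fit_logistic(df, "y", ["exposure"], covariates=())

    def test_constant_exposure_reduces_to_covariate_model(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "score": np.zeros(500),
                "z": rng.standard_normal(500),
                "y": (rng.random(500) < 0.3).astype(float),
            }
        )
        with pytest.warns(UserWarning, match="constant exposure"):
            fit = pr.fit_logistic(df, "y", ["score"], covariates=("z",))
        ref = pr.fit_logistic(df.assign(score=df["z"]), "y", ["z"], covariates=())
        assert fit.llf == pytest.approx(ref.llf, abs=1e-8)

    def test_continuous_score_parameter_recovery(self):
        """A cohort generated with per-unit score log-odds ln(1.38) returns
        an estimate within 3 SE of the generating value."""
        spec = pr.CohortSpec(
            n_subjects=20000, missingness={}, outcome_missingness={}, seed=21
        )
        cohort = pr.generate_cohort(spec)
        frame = pd.concat(
            [
                cohort[["sex", "age_baseline"]],
                pr.score_cohort(pr.binarize(cohort), schemes=("updated_pers",)),
                pr.derive_outcomes(cohort["pq16_total"], cohort["ps_flag"]),
            ],
            axis=1,
        )
        fit = pr.fit_logistic(frame, "ps_flag", ["pers_scaled"])
        truth = spec.outcome_model.beta_per_unit_score
        assert abs(fit.params["pers_scaled"] - truth) < 3 * fit.bse["pers_scaled"]


class TestBandModel:
    @staticmethod
    def _band_cohort(band_log_odds, n=20000, seed=22):
        spec = pr.CohortSpec(
            n_subjects=n,
            missingness={},
            outcome_missingness={},
            oversampling=None,
            seed=seed,
            outcome_model=pr.OutcomeModel(intercept=-2.2, band_log_odds=band_log_odds),
        )
        cohort = pr.generate_cohort(spec)
        return pd.concat(
            [
                cohort[["sex", "age_baseline"]],
                pr.score_cohort(pr.binarize(cohort), schemes=("updated_pers",)),
                pr.derive_outcomes(cohort["pq16_total"], cohort["ps_flag"]),
            ],
            axis=1,
        )

    def test_dose_response_recovery(self):
        """Band effects near the published magnitudes (2.2-fold for 3-4,
        5.2-fold for >=4) are recovered within 3 SE."""
        truth = {
            "1-2": math.log(1.4),
            "2-3": math.log(1.45),
            "3-4": math.log(2.23),
            ">=4": math.log(5.18),
        }
        frame = self._band_cohort(truth)
        fit = pr.fit_band_model(frame, "pe_or_ps")
        for band, b in truth.items():
            term = f"band_{band}"
            assert abs(fit.params[term] - b) < 3 * fit.bse[term], band
        assert fit.params["band_>=4"] > fit.params["band_1-2"]

    def test_empty_band_dropped_with_warning(self):
        frame = self._band_cohort({"1-2": 0.3}, n=2000, seed=23)
        frame = frame[frame["band"] != ">=4"]
        with pytest.warns(UserWarning, match=">=4"):
            fit = pr.fit_band_model(frame, "pe_or_ps")
        assert "band_>=4" not in fit.params.index

    def test_empty_reference_band_rejected(self):
        frame = self._band_cohort({"1-2": 0.3}, n=2000, seed=24)
        frame = frame[frame["band"] != "<1"]
        with pytest.raises(ValueError, match="reference band"):
            pr.fit_band_model(frame, "pe_or_ps")


class TestBenjaminiHochberg:
    def test_hand_example(self):
        adjusted = pr.bh_adjust([0.002, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(adjusted, [0.008, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert pr.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_all_ones(self):
        np.testing.assert_allclose(pr.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pr.bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_stepup_properties(self, pvals):
        adjusted = pr.bh_adjust(pvals)
        raw = np.asarray(pvals)
        # adjusted never below raw, and monotone in the raw-p order
        assert np.all(adjusted >= raw - 1e-12)
        order = np.argsort(raw, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-12)
        # BH rejects at least as much as Bonferroni at any level
        alpha = 0.05
        bonf = np.sum(raw <= alpha / len(raw))
        assert np.sum(adjusted <= alpha) >= bonf


class TestNagelkerke:
    def test_closed_form_case(self):
        # (1 - e^-0.5) / (1 - e^-1) = 0.6225
        assert pr.nagelkerke(-5.0, -10.0, 20) == pytest.approx(0.6225, abs=5e-4)

    def test_null_model_gives_zero(self):
        assert pr.nagelkerke(-10.0, -10.0, 50) == 0.0

    def test_perfect_model_gives_one(self):
        assert pr.nagelkerke(0.0, -30.0, 50) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pr.nagelkerke(-1.0, 0.0, 10)
        with pytest.raises(ValueError, match="below the null"):
            pr.nagelkerke(-11.0, -10.0, 10)
        with pytest.raises(ValueError, match="n must"):
            pr.nagelkerke(-1.0, -2.0, 0)


class TestSchemeComparison:
    @staticmethod
    def _scored_frame(n=10000, seed=25):
        cohort = pr.generate_cohort(
            pr.CohortSpec(n_subjects=n, missingness={}, outcome_missingness={}, seed=seed)
        )
        prof = pr.binarize(cohort)
        aux = pr.auxiliary_factors(cohort, prof)
        return pd.concat(
            [
                cohort[["sex", "age_baseline"]],
                pr.score_cohort(pd.concat([prof, aux], axis=1)),
                pr.derive_outcomes(cohort["pq16_total"], cohort["ps_flag"]),
            ],
            axis=1,
        )

    def test_generating_scheme_attains_best_fit(self):
        """Outcomes generated from the updated PERS: the well-specified score
        dominates the misspecified rivals on -2LL and Nagelkerke R²."""
        frame = self._scored_frame()
        comparison = pr.compare_schemes(
            frame,
            {"updated_pers": "pers_scaled", "p_pers": "p_pers_score", "m_pers": "m_pers_score"},
            "pe_or_ps",
        )
        assert comparison.best == "updated_pers"
        tab = comparison.table
        assert tab.loc["updated_pers", "nagelkerke_r2"] == tab["nagelkerke_r2"].max()
        assert tab["n"].nunique() == 1

    def test_identical_scheme_listed_twice(self):
        frame = self._scored_frame(n=2000, seed=26)
        comparison = pr.compare_schemes(
            frame, {"a": "pers_scaled", "b": "pers_scaled"}, "pe_or_ps"
        )
        t = comparison.table
        assert t.loc["a", "minus2ll"] == pytest.approx(t.loc["b", "minus2ll"])

    def test_fewer_than_two_schemes_rejected(self):
        frame = self._scored_frame(n=500, seed=27)
        with pytest.raises(ValueError, match="two schemes"):
            pr.compare_schemes(frame, {"a": "pers_scaled"}, "pe_or_ps")
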