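"""End-to-end analysis as a model/results pair.

:class:`PERSModel` is built from a raw cohort table and owns the analysis
configuration (weight scheme, PE cut-off rule, covariates, scaling).  Its
:meth:`~PERSModel.fit` runs the whole pipeline — binarization, outcome
derivation, chained-equations multiple imputation, per-imputation scoring and
regression, Rubin pooling and Benjamini-Hochberg correction — and returns a
:class:`PERSResults` carrying the pooled estimate table, the scheme
comparison, the sensitivity block and a ``summary()`` view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from .factors import DEFAULT_ADVERSITY_SET, FACTORS, auxiliary_factors, binarize
from .impute import ImputationSpec, PooledFit, impute, pool_estimates
from .outcomes import derive_outcomes
from .schemes import build_scheme
from .scoring import score_cohort

OUTCOME_LABELS = {"pe_or_ps": "pe_or_ps", "pe": "pe_flag", "ps": "ps_flag"}


def _exposure_rows(pooled: PooledFit, terms, outcome, model_name) -> list[dict]:
    rows = []
    for term in terms:
        est = pooled.params[term]
        rows.append(
            {
                "outcome": outcome,
                "model": model_name,
                "term": term,
                "estimate": est,
                "se": pooled.se[term],
                "OR": np.exp(est) if pooled.family == "logistic" else np.nan,
                "ci_low": np.exp(pooled.conf_int.loc[term, "lower"])
                if pooled.family == "logistic"
                else pooled.conf_int.loc[term, "lower"],
                "ci_high": np.exp(pooled.conf_int.loc[term, "upper"])
                if pooled.family == "logistic"
                else pooled.conf_int.loc[term, "upper"],
                "p": pooled.pvalues[term],
                "n": pooled.nobs,
                "m": pooled.m,
            }
        )
    return rows


class PERSModel:
    """Poly-environmental risk-score analysis of one cohort.

    Parameters
    ----------
    cohort
        Raw cohort table (see :func:`persrisk.factors.binarize` for the
        recognised columns, plus ``pq16_total`` and ``ps_flag`` outcomes and
        the ``sex``/``age_baseline``/``age_followup`` covariates).
    pe_cutoff, pe_rule
        Questionnaire threshold defining the PE flag (default ``>= 6``).
    covariates
        Adjustment set for every regression (default sex and baseline age;
        substitute ``age_followup`` to adjust for age at outcome assessment).
    scaling_mode
        ``"normalized"`` (score scaled so its maximum is the factor count) or
        ``"literal"`` (score multiplied by 14 outright).
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        pe_cutoff: int = 6,
        pe_rule: str = "gte",
        covariates=("sex", "age_baseline"),
        scaling_mode: str = "normalized",
        adversity_set=DEFAULT_ADVERSITY_SET,
    ):
        self.cohort = cohort.reset_index(drop=True)
        self.pe_cutoff = pe_cutoff
        self.pe_rule = pe_rule
        self.covariates = tuple(covariates)
        self.scaling_mode = scaling_mode
        self.adversity_set = tuple(adversity_set)

        self.profile = binarize(self.cohort)
        self.aux = auxiliary_factors(self.cohort, self.profile, adversity_set)
        self.outcomes = derive_outcomes(
            self.cohort.get("pq16_total"), self.cohort.get("ps_flag"),
            cutoff=pe_cutoff, pe_rule=pe_rule,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "PERSModel":
        return cls(df, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PERSModel":
        return cls(pd.read_csv(path), **kwargs)

    # -- pipeline pieces -----------------------------------------------------

    def _imputation_frame(self) -> pd.DataFrame:
        frame = pd.concat([self.profile, self.aux], axis=1)
        frame["sex_female"] = (self.cohort["sex"] == "female").astype(float)
        for c in ("age_baseline", "age_followup"):
            if c in self.cohort:
                frame[c] = pd.to_numeric(self.cohort[c], errors="coerce")
        return frame

    def _analysis_frame(self, completed: pd.DataFrame) -> pd.DataFrame:
        scores = score_cohort(completed, scaling_mode=self.scaling_mode)
        out = pd.concat(
            [completed, scores, self.outcomes.loc[completed.index]], axis=1
        )
        out["sex"] = self.cohort.loc[completed.index, "sex"]
        if "pq16_total" in self.cohort:
            out["pq16_total"] = pd.to_numeric(
                self.cohort.loc[completed.index, "pq16_total"], errors="coerce"
            )
        return out

    # -- fitting ---------------------------------------------------------------

    def fit(
        self,
        n_imputations: int = 15,
        n_iterations: int = 10,
        seed: int = 0,
        outcomes=("pe_or_ps", "pe", "ps"),
        sensitivity: bool = True,
        complete_case: bool = True,
    ) -> "PERSResults":
        """Run the pooled analysis.

        Fits, per outcome: one sex/age-adjusted logistic model per risk
        factor, the unweighted ERS, the continuous scaled PERS, and the
        dose-response band model; pools across the imputed datasets by
        Rubin's rules and applies Benjamini-Hochberg correction within each
        outcome's family of tests.  With ``sensitivity`` it adds the
        SMI-excluded PERS, the linear model on the questionnaire total and
        the scheme-fit comparison; with ``complete_case`` a side-by-side
        complete-case analysis of the composite scores.
        """
        spec = ImputationSpec(
            n_imputations=n_imputations, n_iterations=n_iterations, seed=seed
        )
        stack = impute(self._imputation_frame(), spec)
        frames = [self._analysis_frame(c) for c in stack.datasets]

        rows: list[dict] = []
        comparisons: list[pd.DataFrame] = []
        pooled_fits: dict[tuple[str, str], PooledFit] = {}

        for out_name in outcomes:
            col = OUTCOME_LABELS[out_name]
            family_rows: list[dict] = []

            for factor in FACTORS:
                pooled = pool_estimates(
                    [assoc.fit_logistic(f, col, [factor], self.covariates) for f in frames]
                )
                pooled_fits[(out_name, factor)] = pooled
                family_rows += _exposure_rows(pooled, [factor], out_name, "single_factor")

            for model_name, term in (("ers", "ers"), ("pers_continuous", "pers_scaled")):
                pooled = pool_estimates(
                    [assoc.fit_logistic(f, col, [term], self.covariates) for f in frames]
                )
                pooled_fits[(out_name, model_name)] = pooled
                family_rows += _exposure_rows(pooled, [term], out_name, model_name)

            band_fits = [
                assoc.fit_band_model(f, col, "band", self.covariates) for f in frames
            ]
            pooled = pool_estimates(band_fits)
            pooled_fits[(out_name, "pers_bands")] = pooled
            band_terms = [t for t in pooled.params.index if t.startswith("band_")]
            family_rows += _exposure_rows(pooled, band_terms, out_name, "pers_bands")

            adj = assoc.bh_adjust([r["p"] for r in family_rows])
            for r, q in zip(family_rows, adj):
                r["p_bh"] = q
            rows += family_rows

            if sensitivity:
                pooled = pool_estimates(
                    [
                        assoc.fit_logistic(f, col, ["pers_no_smi_scaled"], self.covariates)
                        for f in frames
                    ]
                )
                rows += _exposure_rows(pooled, ["pers_no_smi_scaled"], out_name, "pers_no_smi")
                nsb = [
                    assoc.fit_logistic(
                        pd.concat(
                            [f.drop(columns=["band"]),
                             assoc.band_dummies(f["pers_no_smi_band"])], axis=1
                        ),
                        col,
                        [t for t in (
                            "band_1-2", "band_2-3", "band_3-4", "band_>=4")
                            if (f["pers_no_smi_band"] == t.removeprefix("band_")).any()],
                        self.covariates,
                    )
                    for f in frames
                ]
                pooled = pool_estimates(nsb)
                rows += _exposure_rows(
                    pooled,
                    [t for t in pooled.params.index if t.startswith("band_")],
                    out_name,
                    "pers_no_smi_bands",
                )
                comparisons.append(
                    self._scheme_comparison(frames, col).table.assign(outcome=out_name)
                )

        if sensitivity:
            linear = pool_estimates(
                [
                    assoc.fit_linear(f, "pq16_total", ["pers_scaled"], self.covariates)
                    for f in frames
                ]
            )
            rows += _exposure_rows(linear, ["pers_scaled"], "pe_total", "linear_pe_total")

        cc_table = None
        if complete_case:
            cc_table = self._complete_case(outcomes)

        table = pd.DataFrame(rows)
        comparison = pd.concat(comparisons) if comparisons else None
        return PERSResults(
            model=self,
            table=table,
            pooled_fits=pooled_fits,
            scheme_comparison=comparison,
            complete_case=cc_table,
            stack=stack,
            config={
                "n_imputations": n_imputations,
                "n_iterations": n_iterations,
                "seed": seed,
                "pe_cutoff": self.pe_cutoff,
                "pe_rule": self.pe_rule,
                "covariates": list(self.covariates),
                "scaling_mode": self.scaling_mode,
            },
        )

    def _scheme_comparison(self, frames, outcome_col) -> assoc.ModelComparison:
        """Scheme fit statistics averaged over the imputed datasets."""
        cols = {
            "updated_pers": "pers_scaled",
            "p_pers": "p_pers_score",
            "m_pers": "m_pers_score",
        }
        tables = [
            assoc.compare_schemes(f, cols, outcome_col, self.covariates).table
            for f in frames
        ]
        mean_table = sum(tables[1:], tables[0].copy()) / len(tables)
        return assoc.ModelComparison(table=mean_table, outcome=outcome_col)

    def _complete_case(self, outcomes) -> pd.DataFrame:
        """Composite-score models on subjects with fully observed profiles."""
        frame_full = self._imputation_frame()
        complete = frame_full.notna().all(axis=1)
        frame = self._analysis_frame(frame_full[complete])
        rows = []
        for out_name in outcomes:
            col = OUTCOME_LABELS[out_name]
            for model_name, term in (("ers", "ers"), ("pers_continuous", "pers_scaled")):
                fit = assoc.fit_logistic(frame, col, [term], self.covariates)
                pooled = pool_estimates([fit])
                rows += _exposure_rows(pooled, [term], out_name, model_name)
        table = pd.DataFrame(rows)
        table["method"] = "complete_case"
        return table


@dataclass
class PERSResults:
    """Pooled results of a :class:`PERSModel` fit."""

    model: PERSModel
    table: pd.DataFrame
    pooled_fits: dict
    scheme_comparison: pd.DataFrame | None
    complete_case: pd.DataFrame | None
    stack: object
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        """Human-readable report mirroring the main results-table layout."""
        lines = [
            "Poly-environmental risk score analysis",
            "=" * 54,
            f"n = {len(self.model.cohort)} subjects; "
            f"m = {self.config.get('n_imputations')} imputations; "
            f"covariates: {', '.join(self.config.get('covariates', []))}",
            "",
        ]
        for outcome, sub in self.table.groupby("outcome", sort=False):
            lines.append(f"Outcome: {outcome}")
            lines.append("-" * 54)
            lines.append(f"{'term':<26}{'OR':>7}{'95% CI':>17}{'p':>9}  p_BH")
            for _, r in sub.iterrows():
                ci = f"({r.ci_low:.2f};{r.ci_high:.2f})"
                pbh = f"{r.p_bh:.4f}" if "p_bh" in r and np.isfinite(r.get("p_bh", np.nan)) else "  -  "
                est = r.OR if np.isfinite(r.OR) else r.estimate
                lines.append(
                    f"{r.term:<26}{est:>7.2f}{ci:>17}{r.p:>9.4f}  {pbh}"
                )
            lines.append("")
        if self.scheme_comparison is not None:
            lines.append("Scheme comparison (mean over imputations):")
            lines.append(self.scheme_comparison.to_string(float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)

    def to_csv(self, directory) -> None:
        """Write the tidy results table, scheme comparison, complete-case
        table and a JSON manifest into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / "results.csv", index=False)
        if self.scheme_comparison is not None:
            self.scheme_comparison.to_csv(directory / "scheme_comparison.csv")
        if self.complete_case is not None:
            self.complete_case.to_csv(directory / "complete_case.csv", index=False)
        (directory / "manifest.json").write_text(json.dumps(self.config, indent=2))

    def plot_dose_response(self, outcome: str = "pe_or_ps", ax=None):
        """Plot pooled band ORs with 95% CIs on a log scale."""
        from .plotting import plot_dose_response

        return plot_dose_response(self, outcome=outcome, ax=ax)


def run_full_analysis(cohort: pd.DataFrame, **config) -> PERSResults:
    """One-call convenience wrapper: build a :class:`PERSModel` from a raw
    cohort table and fit it.  ``config`` keys matching the model constructor
    go there; the rest are passed to :meth:`PERSModel.fit`."""
    model_keys = {"pe_cutoff", "pe_rule", "covariates", "scaling_mode", "adversity_set"}
    model_kwargs = {k: v for k, v in config.items() if k in model_keys}
    fit_kwargs = {k: v for k, v in config.items() if k not in model_keys}
    return PERSModel(cohort, **model_kwargs).fit(**fit_kwargs)
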