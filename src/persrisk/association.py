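"""Regression layer: sex/age-adjusted logistic (and linear) fits, dose-response
band models, Benjamini-Hochberg correction, Nagelkerke pseudo-R² and
model-fit comparison between weight schemes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .scoring import BAND_LABELS

__all__ = [
    "FitResult",
    "ModelComparison",
    "fit_logistic",
    "fit_linear",
    "fit_band_model",
    "bh_adjust",
    "nagelkerke",
    "compare_schemes",
]

DEFAULT_COVARIATES = ("sex", "age_baseline")


@dataclass
class FitResult:
    """A single-dataset regression fit in pooled-analysis-ready form."""

    family: str
    outcome: str
    terms: tuple
    covariates: tuple
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    nobs: int
    llf: float = np.nan
    llnull: float = np.nan
    separation: bool = False

    @property
    def minus2ll(self) -> float:
        return -2.0 * self.llf

    @property
    def nagelkerke_r2(self) -> float:
        if self.family != "logistic" or not np.isfinite(self.llnull):
            return np.nan
        return nagelkerke(self.llf, self.llnull, self.nobs)

    @property
    def odds_ratios(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "ci_low": np.exp(self.conf_int["lower"]),
                "ci_high": np.exp(self.conf_int["upper"]),
                "p": self.pvalues,
            }
        )


def _encode_covariates(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design columns for the adjustment set (sex dummy-coded female=1)."""
    out = pd.DataFrame(index=df.index)
    for c in covariates:
        if c == "sex":
            out["sex_female"] = (df["sex"] == "female").astype(float)
        else:
            out[c] = pd.to_numeric(df[c], errors="coerce")
    return out


def _assemble(df, outcome, terms, covariates):
    y = pd.to_numeric(df[outcome], errors="coerce")
    X = pd.concat([df[list(terms)].astype(float), _encode_covariates(df, covariates)], axis=1)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    X = sm.add_constant(X, has_constant="add")
    return y, X


def fit_logistic(
    df: pd.DataFrame,
    outcome: str,
    terms,
    covariates=DEFAULT_COVARIATES,
) -> FitResult:
    """Maximum-likelihood logistic regression of a binary outcome on exposure
    ``terms``, adjusted for the covariates (default sex and baseline age).

    Wald confidence intervals; rows with any missing value in the used
    columns are dropped.  Separation is flagged (huge coefficients) and the
    fit reported with a warning rather than discarded.
    """
    terms = [terms] if isinstance(terms, str) else list(terms)
    y, X = _assemble(df, outcome, terms, covariates)
    degenerate = [t for t in terms if X[t].nunique() <= 1]
    if degenerate:
        # a constant exposure carries no information; the model reduces to
        # the covariates-only fit
        warnings.warn(f"constant exposure terms dropped: {degenerate}")
        X = X.drop(columns=degenerate)
    classes = set(y.unique())
    if not classes <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} is not binary: {sorted(classes)[:5]}")
    if len(classes) < 2:
        raise ValueError(f"outcome {outcome!r} has a single class in the analysis sample")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # IRLS with pseudo-inverse tolerates near-degenerate designs that
        # would make a Newton solve raise outright
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    separation = bool(np.abs(res.params.drop("const", errors="ignore")).max() > 15)
    if separation:
        warnings.warn(
            f"possible separation fitting {outcome!r} ~ {terms}; "
            "coefficients reported but unstable"
        )
    ci = res.conf_int()
    ci.columns = ["lower", "upper"]
    # intercept-only binomial log-likelihood in closed form
    pbar = float(y.mean())
    llnull = float(
        len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    )
    return FitResult(
        family="logistic",
        outcome=outcome,
        terms=tuple(terms),
        covariates=tuple(covariates),
        params=res.params,
        bse=res.bse,
        conf_int=ci,
        pvalues=res.pvalues,
        nobs=int(res.nobs),
        llf=float(res.llf),
        llnull=llnull,
        separation=separation,
    )


def fit_linear(
    df: pd.DataFrame,
    outcome: str,
    terms,
    covariates=DEFAULT_COVARIATES,
) -> FitResult:
    """Ordinary least squares for the continuous-outcome sensitivity model."""
    terms = [terms] if isinstance(terms, str) else list(terms)
    y, X = _assemble(df, outcome, terms, covariates)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int()
    ci.columns = ["lower", "upper"]
    return FitResult(
        family="linear",
        outcome=outcome,
        terms=tuple(terms),
        covariates=tuple(covariates),
        params=res.params,
        bse=res.bse,
        conf_int=ci,
        pvalues=res.pvalues,
        nobs=int(res.nobs),
        llf=float(res.llf),
    )


def band_dummies(bands: pd.Series, reference: str = BAND_LABELS[0]) -> pd.DataFrame:
    """Dummy-code dose-response bands against the reference band, dropping
    empty bands with a warning."""
    bands = bands.astype(object)
    present = [b for b in BAND_LABELS if (bands == b).any()]
    if reference not in present:
        raise ValueError(f"reference band {reference!r} is empty")
    empty = [b for b in BAND_LABELS if b not in present]
    if empty:
        warnings.warn(f"empty dose-response bands dropped: {empty}")
    out = pd.DataFrame(index=bands.index)
    for b in present:
        if b == reference:
            continue
        out[f"band_{b}"] = (bands == b).astype(float)
    return out


def fit_band_model(
    df: pd.DataFrame,
    outcome: str,
    band_col: str = "band",
    covariates=DEFAULT_COVARIATES,
) -> FitResult:
    """Dose-response model: one OR per score band versus the lowest band."""
    dummies = band_dummies(df[band_col])
    work = pd.concat([df.drop(columns=[band_col]), dummies], axis=1)
    return fit_logistic(work, outcome, list(dummies.columns), covariates)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nagelkerke(loglik_model: float, loglik_null: float, n: int) -> float:
    """Nagelkerke pseudo-R²:
    ``(1 - exp(2 (LL0 - LL1)/n)) / (1 - exp(2 LL0 / n))``, clipped to [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_null == 0:
        raise ValueError("degenerate null model (log-likelihood 0)")
    if loglik_model < loglik_null - 1e-8:
        raise ValueError("model log-likelihood below the null log-likelihood")
    num = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)
    den = 1.0 - np.exp(2.0 * loglik_null / n)
    return float(np.clip(num / den, 0.0, 1.0))


@dataclass
class ModelComparison:
    """Fit statistics of rival scoring schemes on one common analysis sample."""

    table: pd.DataFrame  # index: scheme; columns: minus2ll, nagelkerke_r2, n
    outcome: str

    @property
    def ranking(self) -> list[str]:
        """Schemes from best fit (lowest -2LL) to worst."""
        return list(self.table.sort_values("minus2ll").index)

    @property
    def best(self) -> str:
        return self.ranking[0]


def compare_schemes(
    scores: pd.DataFrame,
    score_columns: dict[str, str],
    outcome: str,
    covariates=DEFAULT_COVARIATES,
) -> ModelComparison:
    """Fit each scheme's continuous score against the outcome with identical
    covariates on the common complete sample; tabulate -2LL and Nagelkerke R².

    ``score_columns`` maps scheme name -> column in ``scores``.
    """
    if len(score_columns) < 2:
        raise ValueError("need at least two schemes to compare")
    needed = list(dict.fromkeys(score_columns.values()))
    cov_cols = ["sex" if c == "sex" else c for c in covariates]
    common = scores.dropna(subset=needed + [outcome] + cov_cols)
    rows = {}
    for name, col in score_columns.items():
        fit = fit_logistic(common, outcome, [col], covariates)
        rows[name] = {
            "minus2ll": fit.minus2ll,
            "nagelkerke_r2": fit.nagelkerke_r2,
            "n": fit.nobs,
        }
    table = pd.DataFrame(rows).T
    ns = table["n"].unique()
    if len(ns) != 1:
        raise ValueError(f"analysis samples differ across schemes: {ns}")
    return ModelComparison(table=table, outcome=outcome)
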