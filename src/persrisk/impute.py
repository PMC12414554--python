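"""Multiple imputation by chained equations (fully conditional specification)
and Rubin's rules pooling.

The imputer runs ``m`` independent chains, each cycling through the variables
with missing cells in column order.  Each variable is imputed from a Bayesian
draw of its conditional model given the current completions of all other
predictors: binary variables from a logistic regression with coefficients
drawn from the approximate normal posterior, continuous variables from a
Bayesian linear regression or predictive mean matching (PMM).  Observed cells
are never touched, so the ``m`` completed tables differ only where the input
was missing.  A conditional fit that fails (perfect separation, singular
design) falls back to PMM with a warning.

Pooling follows Rubin's rules with the Barnard-Rubin small-sample degrees of
freedom:

    qbar = mean(q_j)                     (pooled estimate)
    Ubar = mean(u_j)                     (within-imputation variance)
    B    = var(q_j, ddof=1)              (between-imputation variance)
    T    = Ubar + (1 + 1/m) B            (total variance)
    lam  = (1 + 1/m) B / T
    nu_old = (m - 1) / lam^2
    nu_obs = (dfcom + 1)/(dfcom + 3) * dfcom * (1 - lam)
    nu   = (1/nu_old + 1/nu_obs)^-1      (reference t distribution)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = ["ImputationSpec", "ImputedStack", "PooledFit", "impute", "pool_estimates"]

#: Variables never imputed unless explicitly requested.
DEFAULT_EXCLUDED = ("pq16_total", "ps_flag", "pe_flag", "pe_or_ps")


@dataclass(frozen=True)
class ImputationSpec:
    """Configuration of the chained-equations run."""

    n_imputations: int = 15
    n_iterations: int = 10
    seed: int = 0
    variable_models: dict | None = None  # variable -> {"logistic","linear","pmm"}
    predictors: dict | None = None       # variable -> list of predictor columns
    exclude: tuple = DEFAULT_EXCLUDED
    pmm_donors: int = 5

    def validate(self) -> None:
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class ImputedStack:
    """``m`` completed copies of a cohort table plus chain diagnostics."""

    datasets: list[pd.DataFrame]
    chain_means: pd.DataFrame  # columns: chain, iteration, variable, mean
    spec: ImputationSpec

    @property
    def m(self) -> int:
        return len(self.datasets)


def _is_binary(series: pd.Series) -> bool:
    vals = series.dropna().unique()
    return len(vals) > 0 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def _design(df: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    X = df[predictors].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), X])


def _draw_coefs(rng, params: np.ndarray, cov: np.ndarray) -> np.ndarray:
    cov = (cov + cov.T) / 2
    jitter = 1e-10 * np.eye(len(params))
    L = np.linalg.cholesky(cov + jitter)
    return params + L @ rng.standard_normal(len(params))


def _pmm_impute(rng, y_obs, X_obs, X_mis, k: int) -> np.ndarray:
    """Predictive mean matching with a Bayesian draw of the linear coefficients."""
    res = sm.OLS(y_obs, X_obs).fit()
    beta = _draw_coefs(rng, res.params, res.cov_params())
    pred_obs = X_obs @ res.params
    pred_mis = X_mis @ beta
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    out = np.empty(len(pred_mis))
    for i, p in enumerate(pred_mis):
        pos = np.searchsorted(sorted_pred, p)
        lo = max(0, pos - k)
        hi = min(len(sorted_pred), pos + k)
        donors = order[lo:hi]
        out[i] = y_obs[rng.choice(donors)]
    return out


def _logistic_impute(rng, y_obs, X_obs, X_mis) -> np.ndarray:
    model = sm.GLM(y_obs, X_obs, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=50)
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 25:
        raise np.linalg.LinAlgError("separation suspected")
    beta = _draw_coefs(rng, res.params.to_numpy() if hasattr(res.params, "to_numpy") else res.params,
                       np.asarray(res.cov_params()))
    p = 1.0 / (1.0 + np.exp(-(X_mis @ beta)))
    return (rng.random(len(p)) < p).astype(float)


def _linear_impute(rng, y_obs, X_obs, X_mis) -> np.ndarray:
    res = sm.OLS(y_obs, X_obs).fit()
    dfres = max(int(res.df_resid), 1)
    sigma2 = res.scale * dfres / stats.chi2.rvs(dfres, random_state=rng)
    cov = np.asarray(res.cov_params()) * sigma2 / res.scale
    beta = _draw_coefs(rng, np.asarray(res.params), cov)
    return X_mis @ beta + rng.standard_normal(len(X_mis)) * np.sqrt(sigma2)


def impute(cohort: pd.DataFrame, spec: ImputationSpec | None = None) -> ImputedStack:
    """Run chained-equations multiple imputation on a (numeric) cohort table.

    Every column with missing cells — except those in ``spec.exclude`` — is
    imputed; by default its predictors are all other columns in the frame.
    Non-numeric columns are carried through untouched and are not used as
    predictors unless binary-codable.

    Returns an :class:`ImputedStack` of ``spec.n_imputations`` completed
    tables from independent chains with distinct sub-seeds.
    """
    spec = spec or ImputationSpec()
    spec.validate()

    numeric = cohort.select_dtypes(include=[np.number])
    targets = [
        c for c in numeric.columns
        if c not in spec.exclude and numeric[c].isna().any()
    ]
    for c in targets:
        if numeric[c].isna().all():
            raise ValueError(f"variable {c!r} is entirely missing; cannot impute")

    if not targets:
        return ImputedStack(
            datasets=[cohort.copy() for _ in range(spec.n_imputations)],
            chain_means=pd.DataFrame(columns=["chain", "iteration", "variable", "mean"]),
            spec=spec,
        )

    models = dict(spec.variable_models or {})
    for c in targets:
        models.setdefault(c, "logistic" if _is_binary(numeric[c]) else "pmm")

    default_predictors = [c for c in numeric.columns if c not in spec.exclude]

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_imputations)
    datasets, diag = [], []
    for chain, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        work = numeric.copy()
        # hot-deck initialization from the observed marginals
        for c in targets:
            miss = work[c].isna()
            obs = work[c].dropna().to_numpy()
            work.loc[miss, c] = rng.choice(obs, size=int(miss.sum()))
        for it in range(spec.n_iterations):
            for c in targets:
                miss = numeric[c].isna()
                preds = [p for p in (spec.predictors or {}).get(c, default_predictors) if p != c]
                X = _design(work, preds)
                y_obs = work.loc[~miss, c].to_numpy(dtype=float)
                X_obs, X_mis = X[~miss.to_numpy()], X[miss.to_numpy()]
                kind = models[c]
                try:
                    if kind == "logistic":
                        drawn = _logistic_impute(rng, y_obs, X_obs, X_mis)
                    elif kind == "linear":
                        drawn = _linear_impute(rng, y_obs, X_obs, X_mis)
                    elif kind == "pmm":
                        drawn = _pmm_impute(rng, y_obs, X_obs, X_mis, spec.pmm_donors)
                    else:
                        raise ValueError(f"unknown model {kind!r} for {c!r}")
                except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
                    warnings.warn(
                        f"conditional model for {c!r} failed (chain {chain}, "
                        f"iteration {it}); falling back to predictive mean matching"
                    )
                    drawn = _pmm_impute(rng, y_obs, X_obs, X_mis, spec.pmm_donors)
                work.loc[miss, c] = drawn
                diag.append((chain, it, c, float(work[c].mean())))
        completed = cohort.copy()
        completed[numeric.columns] = work
        datasets.append(completed)

    chain_means = pd.DataFrame(diag, columns=["chain", "iteration", "variable", "mean"])
    return ImputedStack(datasets=datasets, chain_means=chain_means, spec=spec)


# ---------------------------------------------------------------------------
# Rubin's rules


@dataclass
class PooledFit:
    """Rubin-pooled regression estimates across imputed datasets."""

    params: pd.Series
    se: pd.Series
    within: pd.Series
    between: pd.Series
    df: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper
    pvalues: pd.Series
    m: int
    nobs: float
    family: str = "logistic"
    outcome: str = ""
    minus2ll: float = np.nan
    nagelkerke_r2: float = np.nan

    @property
    def odds_ratios(self) -> pd.DataFrame:
        """exp-scale estimates with their pooled 95% CIs (logistic fits)."""
        return pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "ci_low": np.exp(self.conf_int["lower"]),
                "ci_high": np.exp(self.conf_int["upper"]),
                "p": self.pvalues,
            }
        )


def pool_estimates(fits: list, alpha: float = 0.05) -> PooledFit:
    """Pool per-dataset fits by Rubin's rules (Barnard-Rubin df).

    ``fits`` are :class:`persrisk.association.FitResult`-like objects exposing
    ``params``, ``bse``, ``nobs`` (and optionally ``llf``/fit statistics) with
    identical coefficient indexes.  With a single fit the result is that fit
    unchanged (between-imputation variance 0, complete-data df).
    """
    if len(fits) < 1:
        raise ValueError("need at least one fit to pool")
    index = fits[0].params.index
    for f in fits[1:]:
        if not f.params.index.equals(index):
            raise ValueError("mismatched coefficient sets across imputations")

    m = len(fits)
    q = np.vstack([np.asarray(f.params, dtype=float) for f in fits])
    u = np.vstack([np.asarray(f.bse, dtype=float) ** 2 for f in fits])

    qbar = q.mean(axis=0)
    ubar = u.mean(axis=0)
    if m > 1:
        b = q.var(axis=0, ddof=1)
    else:
        b = np.zeros_like(qbar)
    t = ubar + (1 + 1 / m) * b

    nobs = float(np.mean([f.nobs for f in fits]))
    dfcom = max(nobs - len(index), 1.0)
    lam = np.divide((1 + 1 / m) * b, t, out=np.zeros_like(t), where=t > 0)
    safe_lam = np.where(lam > 0, lam, 1.0)
    nu_old = np.where(lam > 0, (m - 1) / safe_lam**2, np.inf)
    nu_obs = (dfcom + 1) / (dfcom + 3) * dfcom * (1 - lam)
    df = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)

    se = np.sqrt(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, qbar / se, np.nan)
    pvals = 2 * stats.t.sf(np.abs(tstat), df)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    ci = pd.DataFrame(
        {"lower": qbar - tcrit * se, "upper": qbar + tcrit * se}, index=index
    )

    m2ll = float(np.mean([getattr(f, "minus2ll", np.nan) for f in fits]))
    r2 = float(np.mean([getattr(f, "nagelkerke_r2", np.nan) for f in fits]))
    return PooledFit(
        params=pd.Series(qbar, index=index),
        se=pd.Series(se, index=index),
        within=pd.Series(ubar, index=index),
        between=pd.Series(b, index=index),
        df=pd.Series(df, index=index),
        conf_int=ci,
        pvalues=pd.Series(pvals, index=index),
        m=m,
        nobs=nobs,
        family=getattr(fits[0], "family", "logistic"),
        outcome=getattr(fits[0], "outcome", ""),
        minus2ll=m2ll,
        nagelkerke_r2=r2,
    )
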