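"""Synthetic adolescent cohorts with the statistical structure the risk-score
analysis assumes.

The generator draws the 14 binary exposures from a Gaussian copula
(dichotomized latent normals, copula correlations solved numerically so the
binary pair attains a requested phi coefficient), synthesizes raw measurement
columns consistent with each binary truth (so :func:`persrisk.factors.binarize`
recovers the generated profile exactly), selects subjects through a
screening-instrument oversampling design (high scorers oversampled at a
configurable ratio), draws psychotic-experience and psychotic-symptom outcomes
from a logistic model on the subject's true composite score, and finally masks
exposures at the study's missingness rates.

Default parameters are the study conditions: exposure prevalences and
per-variable missing counts from the cohort's descriptive table (n=801),
one strongly correlated exposure pair (gestational age / birth weight,
phi = .57) with otherwise low correlations, top-15% screening oversampling at
2.5:1, ages 14.94 (0.91) at baseline and 18.07 (0.85) at follow-up, and an
outcome model calibrated to a 21.5% combined PE/PS prevalence with a per-unit
scaled-score odds ratio of 1.38.
"""

from __future__ import annotations

import dataclasses
import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .factors import DEFAULT_ADVERSITY_SET, FACTORS, binarize
from .schemes import build_scheme
from .scoring import band_of, scale_pers, score_weighted

__all__ = [
    "OutcomeModel",
    "Oversampling",
    "CohortSpec",
    "InfeasibleCorrelationError",
    "generate_cohort",
    "generate_population",
    "apply_oversampling",
    "inject_missingness",
    "calibrate_intercept",
    "latent_rho_for_phi",
    "phi_coefficient",
    "TABLE_PREVALENCES",
    "DEFAULT_MISSINGNESS",
    "DEFAULT_CORRELATION_PAIRS",
]


class InfeasibleCorrelationError(ValueError):
    """A requested binary correlation cannot be realized for the margins."""


#: Study exposure prevalences (descriptive-table proportions, n = 801).
TABLE_PREVALENCES: dict[str, float] = {
    "winter_birth": 0.207,
    "low_gestational_age": 0.086,
    "low_birth_weight": 0.074,
    "ethnic_minority": 0.175,
    "urban": 0.787,
    "cannabis": 0.066,
    "bullied": 0.112,
    "emotional_abuse": 0.223,
    "physical_abuse": 0.229,
    "sexual_abuse": 0.056,
    "high_paternal_age": 0.404,
    "parental_divorce": 0.242,
    "parental_smi": 0.304,
    "parental_death": 0.008,
}

#: Per-variable missing proportions (study missing counts / 801), keyed by raw
#: cohort column or alias understood by :func:`inject_missingness`.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "gestational_age": 229 / 801,
    "birth_weight": 262 / 801,
    "ethnic_background": 3 / 801,
    "cannabis_ever": 3 / 801,
    "bullied_multiple": 72 / 801,
    "emotional_abuse": 53 / 801,
    "physical_abuse": 95 / 801,
    "sexual_abuse": 85 / 801,
    "paternal_age_at_birth": 284 / 801,
    "parental_divorce": 71 / 801,
    "parental_smi": 78 / 801,
    "parental_death": 70 / 801,
}

#: One strong perinatal pair, otherwise low adversity correlations.
DEFAULT_CORRELATION_PAIRS: tuple[tuple[str, str, float], ...] = (
    ("low_gestational_age", "low_birth_weight", 0.57),
    ("bullied", "emotional_abuse", 0.10),
    ("emotional_abuse", "physical_abuse", 0.10),
    ("physical_abuse", "sexual_abuse", 0.10),
    ("parental_divorce", "emotional_abuse", 0.10),
)

#: Columns that :func:`inject_missingness` expands to their raw inputs.
_MISSINGNESS_ALIASES: dict[str, tuple[str, ...]] = {
    "emotional_abuse": ("psych_aggression_adolescent", "psych_aggression_parent"),
    "ethnic_background": ("parent1_region", "parent2_region"),
    "bullying": ("bullied_multiple",),
    "cannabis": ("cannabis_ever",),
    "paternal_age": ("paternal_age_at_birth",),
}

_OUTCOME_COLUMNS = ("pq16_total", "ps_flag")


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic outcome model on the subject's true (pre-missingness) score.

    ``logit P = intercept + beta_per_unit_score * scaled_score
    + beta_sex * female + beta_age * (age_baseline - 15)``.
    PE and PS are drawn independently from the same model; with
    ``band_log_odds`` set, the score term is replaced by a per-band effect
    (dose-response generation).  The default intercept was produced by
    :func:`calibrate_intercept` targeting a 21.5% combined PE/PS prevalence.
    """

    intercept: float = -3.283
    beta_per_unit_score: float = 0.3221  # ln(1.38) per unit of the 0-14 score
    beta_sex: float = 0.0
    beta_age: float = 0.0
    band_log_odds: dict | None = None


@dataclass(frozen=True)
class Oversampling:
    """Screening-based design: subjects above the ``top_fraction`` quantile of
    the screening score are sampled with ``ratio`` times the probability of
    those below."""

    top_fraction: float = 0.15
    ratio: float = 2.5
    population_factor: float = 4.0  # generated population size / cohort size

    def validate(self) -> None:
        if not 0 < self.top_fraction < 1:
            raise ValueError(f"top_fraction must be in (0,1), got {self.top_fraction}")
        if not self.ratio > 0:
            raise ValueError(f"ratio must be positive, got {self.ratio}")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for a synthetic cohort."""

    n_subjects: int = 801
    factor_prevalences: dict = field(default_factory=lambda: dict(TABLE_PREVALENCES))
    correlation_pairs: tuple = DEFAULT_CORRELATION_PAIRS
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    # outcomes are masked at the study's follow-up non-response rates but are
    # never imputed downstream (PE questionnaire 1.2%, clinician interview 9.0%)
    outcome_missingness: dict = field(
        default_factory=lambda: {"pq16_total": 0.012, "ps_flag": 0.090}
    )
    oversampling: Oversampling | None = field(default_factory=Oversampling)
    screening_r: float = 0.3  # latent corr. of the screening score w/ adversity
    sex_female_prop: float = 0.536
    age_baseline: tuple[float, float] = (14.94, 0.91)  # mean, SD; truncated +-3 SD
    age_followup: tuple[float, float] = (18.07, 0.85)
    scaling_mode: str = "normalized"
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        unknown = set(self.factor_prevalences) - set(FACTORS)
        if unknown:
            raise ValueError(f"unknown factors in prevalences: {sorted(unknown)}")
        for f in FACTORS:
            p = self.factor_prevalences.get(f)
            if p is None or not 0 <= p <= 1:
                raise ValueError(f"prevalence for {f!r} must be in [0,1], got {p}")
        for a, b, r in self.correlation_pairs:
            if a not in FACTORS or b not in FACTORS:
                raise ValueError(f"correlation pair names unknown factor: ({a}, {b})")
            if not abs(r) < 1:
                raise ValueError(f"|r| must be < 1 for pair ({a}, {b}), got {r}")
        for rates in (self.missingness, self.outcome_missingness):
            for v, rate in rates.items():
                if not 0 <= rate <= 1:
                    raise ValueError(f"missingness rate for {v!r} must be in [0,1]")
        if self.oversampling is not None:
            self.oversampling.validate()


# ---------------------------------------------------------------------------
# Gaussian copula machinery


def phi_coefficient(x, y) -> float:
    """Sample phi (Pearson) correlation of two binary arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.corrcoef(x, y)[0, 1])


def _phi_from_rho(rho: float, p1: float, p2: float) -> float:
    """Phi coefficient of dichotomized bivariate normals with latent corr rho."""
    t1, t2 = stats.norm.ppf(1 - p1), stats.norm.ppf(1 - p2)
    if abs(rho) >= 1:
        rho = np.sign(rho) * 0.9999
    p11 = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
    ).cdf([-t1, -t2])  # P(Z1 > t1, Z2 > t2) by symmetry
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return float((p11 - p1 * p2) / denom)


@functools.lru_cache(maxsize=512)
def latent_rho_for_phi(p1: float, p2: float, phi: float) -> float:
    """Copula (tetrachoric-style) correlation giving binary phi ``phi`` at the
    margins ``p1``, ``p2``; raises :class:`InfeasibleCorrelationError` when no
    latent correlation can realize it."""
    if phi == 0:
        return 0.0
    lo, hi = _phi_from_rho(-0.999, p1, p2), _phi_from_rho(0.999, p1, p2)
    if not lo - 1e-9 <= phi <= hi + 1e-9:
        raise InfeasibleCorrelationError(
            f"phi={phi} infeasible for margins ({p1}, {p2}); "
            f"attainable range is [{lo:.3f}, {hi:.3f}]"
        )
    return float(
        optimize.brentq(lambda r: _phi_from_rho(r, p1, p2) - phi, -0.999, 0.999)
    )


def _latent_correlation(spec: CohortSpec) -> np.ndarray:
    """Latent correlation matrix over the 14 factors + the screening score."""
    names = list(FACTORS) + ["screening"]
    k = len(names)
    corr = np.eye(k)
    seen = set()
    for a, b, r in spec.correlation_pairs:
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"duplicate correlation pair ({a}, {b})")
        seen.add(key)
        rho = latent_rho_for_phi(
            spec.factor_prevalences[a], spec.factor_prevalences[b], r
        )
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = rho
    s = names.index("screening")
    for f in DEFAULT_ADVERSITY_SET:
        i = names.index(f)
        if corr[i, s] == 0:
            corr[i, s] = corr[s, i] = spec.screening_r
    if np.linalg.eigvalsh(corr).min() < 1e-8:
        raise InfeasibleCorrelationError(
            "requested correlation pairs are not jointly feasible "
            "(latent correlation matrix is not positive definite)"
        )
    return corr


# ---------------------------------------------------------------------------
# Raw-variable synthesis (consistent with the binary truth)


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


_WINTER_DAYS = 90       # Dec 21 - Mar 20 in a non-leap year
_NON_WINTER_DAYS = 275  # Mar 21 - Dec 20


def _birth_dates(rng, winter: np.ndarray) -> pd.Series:
    n = len(winter)
    winter_start = pd.Timestamp("2002-12-21")
    rest_start = pd.Timestamp("2003-03-21")
    offs_w = rng.integers(0, _WINTER_DAYS, size=n)
    offs_r = rng.integers(0, _NON_WINTER_DAYS, size=n)
    dates = np.where(
        winter == 1,
        winter_start.to_datetime64() + offs_w * np.timedelta64(1, "D"),
        rest_start.to_datetime64() + offs_r * np.timedelta64(1, "D"),
    )
    return pd.Series(pd.DatetimeIndex(dates).normalize())


def _raw_from_truth(rng, truth: pd.DataFrame) -> pd.DataFrame:
    """Raw measurement columns whose binarization equals ``truth`` exactly."""
    n = len(truth)
    df = pd.DataFrame(index=truth.index)
    df["birth_date"] = _birth_dates(rng, truth["winter_birth"].to_numpy()).to_numpy()

    lga = truth["low_gestational_age"].to_numpy() == 1
    ga = _truncated_normal(rng, 39.5, 1.3, 37.0, 43.0, n)
    ga[lga] = _truncated_normal(rng, 34.5, 1.8, 25.0, 36.9, int(lga.sum()))
    df["gestational_age"] = np.round(ga, 1)

    lbw = truth["low_birth_weight"].to_numpy() == 1
    bw = _truncated_normal(rng, 3450, 450, 2500, 5200, n)
    bw[lbw] = _truncated_normal(rng, 2100, 300, 600, 2499, int(lbw.sum()))
    df["birth_weight"] = np.round(bw)

    minority = truth["ethnic_minority"].to_numpy() == 1
    both_nw = minority & (rng.random(n) < 0.3)
    which = rng.random(n) < 0.5
    p1 = np.where(minority & (both_nw | which), "non_western", "western")
    p2 = np.where(minority & (both_nw | ~which), "non_western", "western")
    df["parent1_region"] = p1
    df["parent2_region"] = p2

    urban = truth["urban"].to_numpy() == 1
    dens = np.exp(rng.normal(np.log(500.0), 0.5, n)).clip(10, 999)
    dens[urban] = np.exp(rng.normal(np.log(3000.0), 0.5, int(urban.sum()))).clip(1001, 30000)
    df["address_density"] = np.round(dens)

    df["cannabis_ever"] = truth["cannabis"].astype(float).to_numpy()
    df["bullied_multiple"] = truth["bullied"].astype(float).to_numpy()

    ea = truth["emotional_abuse"].to_numpy() == 1
    u = rng.random(n)
    df["psych_aggression_adolescent"] = (ea & (u < 0.6)).astype(float)
    df["psych_aggression_parent"] = (ea & (u >= 0.4)).astype(float)

    df["physical_abuse"] = truth["physical_abuse"].astype(float).to_numpy()
    df["sexual_abuse"] = truth["sexual_abuse"].astype(float).to_numpy()

    hpa = truth["high_paternal_age"].to_numpy() == 1
    pa = _truncated_normal(rng, 29.5, 3.5, 17.0, 35.0, n)
    pa[hpa] = _truncated_normal(rng, 41.0, 3.5, 35.1, 60.0, int(hpa.sum()))
    df["paternal_age_at_birth"] = np.round(pa, 1)

    df["parental_divorce"] = truth["parental_divorce"].astype(float).to_numpy()
    df["parental_smi"] = truth["parental_smi"].astype(float).to_numpy()
    df["parental_death"] = truth["parental_death"].astype(float).to_numpy()
    return df


# ---------------------------------------------------------------------------
# Outcomes


def _linear_predictor(model: OutcomeModel, scaled_score, raw_score, female, age_baseline):
    eta = model.intercept + model.beta_sex * female + model.beta_age * (age_baseline - 15.0)
    if model.band_log_odds is not None:
        bands = band_of(np.asarray(raw_score, dtype=float))
        effect = np.array([model.band_log_odds.get(b, 0.0) for b in np.atleast_1d(bands)])
        return eta + effect
    return eta + model.beta_per_unit_score * np.asarray(scaled_score, dtype=float)


def _draw_outcomes(rng, model, scaled_score, raw_score, female, age_baseline):
    eta = _linear_predictor(model, scaled_score, raw_score, female, age_baseline)
    p = 1.0 / (1.0 + np.exp(-eta))
    n = len(p)
    pe_flag = (rng.random(n) < p).astype(int)
    ps_flag = (rng.random(n) < p).astype(float)
    # questionnaire total consistent with the PE flag at the >=6 cut-off
    pq16 = rng.binomial(5, 0.3, size=n).astype(float)
    pq16[pe_flag == 1] = 6 + rng.binomial(10, 0.25, size=int(pe_flag.sum()))
    return pq16, ps_flag


# ---------------------------------------------------------------------------
# Public generation API


def generate_population(spec: CohortSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Generate ``n`` subjects (no oversampling, no missingness).

    Includes the latent ``screening_score`` used by the oversampling design
    and the drawn outcomes (``pq16_total``, ``ps_flag``).
    """
    spec.validate()
    corr = _latent_correlation(spec)
    z = rng.multivariate_normal(np.zeros(corr.shape[0]), corr, size=n, method="cholesky")
    thresholds = stats.norm.ppf(
        [1 - spec.factor_prevalences[f] for f in FACTORS]
    )
    truth = pd.DataFrame(
        (z[:, : len(FACTORS)] > thresholds).astype(float), columns=list(FACTORS)
    )
    screening = z[:, -1]

    df = pd.DataFrame({"id": np.arange(n)})
    df["sex"] = np.where(rng.random(n) < spec.sex_female_prop, "female", "male")
    m0, s0 = spec.age_baseline
    m1, s1 = spec.age_followup
    df["age_baseline"] = np.round(_truncated_normal(rng, m0, s0, m0 - 3 * s0, m0 + 3 * s0, n), 2)
    df["age_followup"] = np.round(_truncated_normal(rng, m1, s1, m1 - 3 * s1, m1 + 3 * s1, n), 2)

    raw = _raw_from_truth(rng, truth)
    df = pd.concat([df, raw], axis=1)
    df["screening_score"] = np.round(screening, 4)

    scheme = build_scheme("updated_pers")
    pers_raw = score_weighted(truth, scheme)
    pers_scaled = scale_pers(pers_raw, scheme, mode=spec.scaling_mode)
    female = (df["sex"] == "female").to_numpy(dtype=float)
    pq16, ps = _draw_outcomes(
        rng, spec.outcome_model, pers_scaled.to_numpy(), pers_raw.to_numpy(),
        female, df["age_baseline"].to_numpy(),
    )
    df["pq16_total"] = pq16
    df["ps_flag"] = ps
    return df


def apply_oversampling(
    population: pd.DataFrame,
    top_fraction: float,
    ratio: float,
    size: int,
    seed: int | np.random.Generator,
    score_col: str = "screening_score",
) -> pd.DataFrame:
    """Sample ``size`` subjects, those above the ``top_fraction`` screening
    quantile with ``ratio`` times the sampling probability of the rest.

    Subjects are retained independently with probability proportional to
    their weight and a simple random sample of the requested size is drawn
    from the retained pool, so the expected high-scorer share is
    ``t*r / (t*r + 1 - t)``.
    """
    Oversampling(top_fraction, ratio).validate()
    if size > len(population):
        raise ValueError(
            f"requested cohort of {size} exceeds population of {len(population)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = population[score_col].to_numpy(dtype=float)
    cutoff = np.quantile(scores, 1 - top_fraction)
    high = scores > cutoff
    weights = np.where(high, ratio, 1.0)
    accept = rng.random(len(population)) < weights / weights.max()
    pool = population.index[accept]
    if len(pool) < size:
        raise ValueError(
            f"population too small for the oversampling design: only "
            f"{len(pool)} subjects retained, {size} requested"
        )
    chosen = rng.choice(pool, size=size, replace=False)
    return population.loc[np.sort(chosen)].reset_index(drop=True)


def inject_missingness(
    cohort: pd.DataFrame,
    missingness: dict[str, float],
    seed: int | np.random.Generator,
    mar_strength: float = 0.0,
    allow_outcomes: bool = False,
) -> pd.DataFrame:
    """Mask exposure cells at the requested per-variable rates.

    Keys are raw cohort columns or aliases (``emotional_abuse`` masks both
    informant columns together; ``ethnic_background`` both parent regions).
    With ``mar_strength`` > 0 the missingness probability depends on the
    fully observed covariates (sex, baseline age) while preserving the
    overall rate — a missing-at-random mechanism.  Outcome columns are
    refused unless ``allow_outcomes`` is set.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)

    if mar_strength:
        z_age = stats.zscore(out["age_baseline"].to_numpy(dtype=float))
        female = (out["sex"] == "female").to_numpy(dtype=float)
        w = np.exp(mar_strength * (z_age + female))
        w /= w.mean()
    else:
        w = np.ones(n)

    for key, rate in missingness.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"missingness rate for {key!r} must be in [0,1]")
        cols = _MISSINGNESS_ALIASES.get(key, (key,))
        for col in cols:
            if col not in out.columns:
                raise ValueError(f"unknown variable in missingness map: {key!r}")
            if col in _OUTCOME_COLUMNS and not allow_outcomes:
                raise ValueError(
                    f"outcome variable {col!r} is never masked by default; "
                    "pass allow_outcomes=True to override"
                )
        if rate == 0:
            continue
        mask = rng.random(n) < np.clip(rate * w, 0, 1)
        for col in cols:
            out[col] = out[col].mask(mask)
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a full synthetic cohort per ``spec``: population draw,
    screening oversampling (if configured) and missingness injection.

    Deterministic: the same spec (including seed) yields an identical frame.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.oversampling is not None:
        n_pop = int(np.ceil(spec.n_subjects * spec.oversampling.population_factor))
        population = generate_population(spec, n_pop, rng)
        cohort = apply_oversampling(
            population,
            spec.oversampling.top_fraction,
            spec.oversampling.ratio,
            spec.n_subjects,
            rng,
        )
        cohort["id"] = np.arange(len(cohort))
    else:
        cohort = generate_population(spec, spec.n_subjects, rng)
    if spec.missingness:
        cohort = inject_missingness(cohort, spec.missingness, rng)
    if spec.outcome_missingness:
        cohort = inject_missingness(
            cohort, spec.outcome_missingness, rng, allow_outcomes=True
        )
    return cohort


def calibrate_intercept(
    spec: CohortSpec,
    target_prevalence: float = 0.215,
    n_sim: int = 20000,
    seed: int = 0,
) -> float:
    """Solve for the outcome-model intercept that yields ``target_prevalence``
    for the combined PE/PS outcome under ``spec``'s score distribution.

    Works on a large simulated cohort (missingness off): with PE and PS drawn
    independently from the same logistic model, the combined prevalence is
    ``E[1 - (1 - sigmoid(eta))^2]``, monotone in the intercept.
    """
    if not 0 < target_prevalence < 1:
        raise ValueError("target_prevalence must be in (0,1)")
    sim_spec = dataclasses.replace(
        spec, n_subjects=n_sim, missingness={}, seed=seed
    )
    cohort = generate_cohort(sim_spec)
    truth = binarize(cohort)
    scheme = build_scheme("updated_pers")
    raw = score_weighted(truth, scheme)
    scaled = scale_pers(raw, scheme, mode=spec.scaling_mode)
    female = (cohort["sex"] == "female").to_numpy(dtype=float)
    age = cohort["age_baseline"].to_numpy(dtype=float)
    model = spec.outcome_model

    def combined(intercept: float) -> float:
        m = dataclasses.replace(model, intercept=intercept)
        eta = _linear_predictor(m, scaled.to_numpy(), raw.to_numpy(), female, age)
        p = 1.0 / (1.0 + np.exp(-eta))
        return float(np.mean(1 - (1 - p) ** 2))

    return float(
        optimize.brentq(lambda c: combined(c) - target_prevalence, -20.0, 20.0)
    )
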