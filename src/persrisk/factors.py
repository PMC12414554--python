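"""Binarization of raw exposure variables into the 14 environmental risk factors.

Each factor is a tri-state indicator: 1.0 (present), 0.0 (absent) or NaN
(missing).  A factor is missing only when *every* raw input its rule needs is
missing; for disjunctive rules (ethnic minority, emotional abuse) a single
observed informant/parent is enough to decide the indicator.

Cut-offs:

====================  =======================================================
winter_birth          born between December 21st and March 20th (inclusive),
                      astronomical seasons anchored on the 21st of the month
low_gestational_age   gestational age < 37 weeks
low_birth_weight      birth weight < 2500 g
ethnic_minority       at least one parent born in a non-Western country
urban                 surrounding address density > 1000 addresses / km^2
cannabis              has ever used cannabis
bullied               has been bullied multiple times (pre-derived flag)
emotional_abuse       "often" on >= 1 psychological-aggression item by either
                      informant (adolescent or parent)
physical_abuse        parent-reported, present/absent
sexual_abuse          parent-reported, present/absent
high_paternal_age     paternal age > 35 years at the child's birth
parental_divorce      present/absent
parental_smi          lifetime parental severe mental illness (major
                      depressive, bipolar or psychotic disorder)
parental_death        present/absent
====================  =======================================================
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable

import numpy as np
import pandas as pd

#: Canonical order of the 14 risk factors.
FACTORS: tuple[str, ...] = (
    "winter_birth",
    "low_gestational_age",
    "low_birth_weight",
    "ethnic_minority",
    "urban",
    "cannabis",
    "bullied",
    "emotional_abuse",
    "physical_abuse",
    "sexual_abuse",
    "high_paternal_age",
    "parental_divorce",
    "parental_smi",
    "parental_death",
)

#: Auxiliary binarized factors required by the historical comparator schemes.
AUX_FACTORS: tuple[str, ...] = (
    "winter_or_spring_birth",   # P-PERS season factor
    "paternal_age_40_50",       # M-PERS paternal-age factor (40-50 years)
    "any_childhood_adversity",  # M-PERS adversity factor
)

#: Factors counted as "childhood adversity" for the M-PERS adversity item.
DEFAULT_ADVERSITY_SET: tuple[str, ...] = (
    "bullied",
    "emotional_abuse",
    "physical_abuse",
    "sexual_abuse",
    "parental_divorce",
    "parental_death",
)

SEASONS = ("winter", "spring", "summer", "autumn")

# (start_month, season starting on the 21st of that month)
_SEASON_STARTS = {12: "winter", 3: "spring", 6: "summer", 9: "autumn"}


def season_of(date) -> str:
    """Astronomical season of a calendar date, seasons starting on the 21st.

    Winter is Dec 21 - Mar 20, spring Mar 21 - Jun 20, summer Jun 21 - Sep 20,
    autumn Sep 21 - Dec 20; every date maps to exactly one season.  Feb 29
    falls in winter.
    """
    date = pd.Timestamp(date)
    m, d = date.month, date.day
    if m in (12, 3, 6, 9):
        start = _SEASON_STARTS[m]
        if d >= 21:
            return start
        # before the 21st we are still in the previous season
        return SEASONS[(SEASONS.index(start) - 1) % 4]
    if m in (1, 2):
        return "winter"
    if m in (4, 5):
        return "spring"
    if m in (7, 8):
        return "summer"
    return "autumn"  # 10, 11


def _seasons_series(dates: pd.Series) -> pd.Series:
    dates = pd.to_datetime(dates, errors="coerce")
    out = pd.Series(pd.NA, index=dates.index, dtype="object")
    ok = dates.notna()
    out.loc[ok] = [season_of(d) for d in dates[ok]]
    return out


def _tri_threshold(values: pd.Series, predicate) -> pd.Series:
    """Apply ``predicate`` where observed, NaN elsewhere."""
    values = pd.to_numeric(values, errors="coerce")
    out = pd.Series(np.nan, index=values.index, dtype=float)
    ok = values.notna()
    out.loc[ok] = predicate(values[ok]).astype(float)
    return out


def _tri_flag(values: pd.Series) -> pd.Series:
    """Interpret a {0,1,True,False,NaN} column as a tri-state indicator."""
    values = pd.to_numeric(values, errors="coerce")
    bad = values.dropna()[~values.dropna().isin([0, 1])]
    if len(bad):
        raise ValueError(f"flag column contains non-binary values: {bad.unique()[:5]}")
    return values.astype(float)


def _tri_any(columns: list[pd.Series]) -> pd.Series:
    """Tri-state disjunction: present if any observed input is positive,
    absent if at least one input is observed and none is positive, missing
    iff all inputs are missing."""
    mat = pd.concat(columns, axis=1)
    any_pos = (mat == 1).any(axis=1)
    all_missing = mat.isna().all(axis=1)
    out = pd.Series(np.nan, index=mat.index, dtype=float)
    out.loc[~all_missing] = 0.0
    out.loc[any_pos] = 1.0
    return out


def _check_positive(df: pd.DataFrame, column: str, strictly: bool = True) -> None:
    if column not in df:
        return
    vals = pd.to_numeric(df[column], errors="coerce").dropna()
    bad = vals <= 0 if strictly else vals < 0
    if bad.any():
        raise ValueError(
            f"impossible value in '{column}': "
            f"{vals[bad].iloc[0]!r} (must be {'>' if strictly else '>='} 0)"
        )


def _region_indicator(values: pd.Series) -> pd.Series:
    """1 for non-Western parental country of birth, 0 for Western, NaN missing."""
    out = pd.Series(np.nan, index=values.index, dtype=float)
    s = values.astype("object")
    out.loc[s == "non_western"] = 1.0
    out.loc[s == "western"] = 0.0
    unknown = s.dropna()[~s.dropna().isin(["western", "non_western"])]
    if len(unknown):
        raise ValueError(f"unknown parent region label: {unknown.iloc[0]!r}")
    return out


def binarize(cohort: pd.DataFrame) -> pd.DataFrame:
    """Convert a raw cohort table into the 14 tri-state risk-factor indicators.

    Parameters
    ----------
    cohort
        One row per adolescent.  Recognised raw columns (all optional in the
        sense that any cell may be missing): ``birth_date``,
        ``gestational_age`` (weeks), ``birth_weight`` (grams),
        ``parent1_region``/``parent2_region`` ({"western","non_western"}),
        ``address_density`` (addresses/km^2), ``cannabis_ever``,
        ``bullied_multiple``, ``psych_aggression_adolescent``/
        ``psych_aggression_parent`` ("often" flags by informant),
        ``physical_abuse``, ``sexual_abuse``, ``paternal_age_at_birth``
        (years), ``parental_divorce``, ``parental_smi``, ``parental_death``.

    Returns
    -------
    DataFrame with the 14 :data:`FACTORS` columns, values in {1.0, 0.0, NaN}.

    Raises
    ------
    ValueError
        on physically impossible raw values (non-positive gestational age,
        birth weight or paternal age; negative address density), naming the
        offending field.
    """
    _check_positive(cohort, "gestational_age")
    _check_positive(cohort, "birth_weight")
    _check_positive(cohort, "paternal_age_at_birth")
    _check_positive(cohort, "address_density", strictly=False)

    idx = cohort.index
    nan = pd.Series(np.nan, index=idx, dtype=float)

    def col(name: str) -> pd.Series:
        return cohort[name] if name in cohort else nan.copy()

    seasons = _seasons_series(col("birth_date"))
    winter = pd.Series(np.nan, index=idx, dtype=float)
    winter.loc[seasons.notna()] = (seasons[seasons.notna()] == "winter").astype(float)

    out = pd.DataFrame(index=idx)
    out["winter_birth"] = winter
    out["low_gestational_age"] = _tri_threshold(col("gestational_age"), lambda v: v < 37)
    out["low_birth_weight"] = _tri_threshold(col("birth_weight"), lambda v: v < 2500)
    out["ethnic_minority"] = _tri_any(
        [_region_indicator(col("parent1_region")), _region_indicator(col("parent2_region"))]
    )
    out["urban"] = _tri_threshold(col("address_density"), lambda v: v > 1000)
    out["cannabis"] = _tri_flag(col("cannabis_ever"))
    out["bullied"] = _tri_flag(col("bullied_multiple"))
    out["emotional_abuse"] = _tri_any(
        [_tri_flag(col("psych_aggression_adolescent")), _tri_flag(col("psych_aggression_parent"))]
    )
    out["physical_abuse"] = _tri_flag(col("physical_abuse"))
    out["sexual_abuse"] = _tri_flag(col("sexual_abuse"))
    out["high_paternal_age"] = _tri_threshold(col("paternal_age_at_birth"), lambda v: v > 35)
    out["parental_divorce"] = _tri_flag(col("parental_divorce"))
    out["parental_smi"] = _tri_flag(col("parental_smi"))
    out["parental_death"] = _tri_flag(col("parental_death"))
    return out[list(FACTORS)]


def auxiliary_factors(
    cohort: pd.DataFrame,
    profile: pd.DataFrame | None = None,
    adversity_set: Iterable[str] = DEFAULT_ADVERSITY_SET,
) -> pd.DataFrame:
    """Derive the auxiliary indicators used by the P-PERS and M-PERS schemes.

    ``winter_or_spring_birth`` and ``paternal_age_40_50`` come from the raw
    cohort columns; ``any_childhood_adversity`` is the tri-state disjunction
    of the ``adversity_set`` factors in ``profile`` (computed from ``cohort``
    if not supplied).
    """
    if profile is None:
        profile = binarize(cohort)
    adversity_set = list(adversity_set)
    unknown = set(adversity_set) - set(FACTORS)
    if unknown:
        raise ValueError(f"unknown adversity factors: {sorted(unknown)}")

    idx = cohort.index
    seasons = _seasons_series(
        cohort["birth_date"] if "birth_date" in cohort else pd.Series(pd.NA, index=idx)
    )
    ws = pd.Series(np.nan, index=idx, dtype=float)
    ws.loc[seasons.notna()] = seasons[seasons.notna()].isin(["winter", "spring"]).astype(float)

    pat = (
        cohort["paternal_age_at_birth"]
        if "paternal_age_at_birth" in cohort
        else pd.Series(np.nan, index=idx)
    )
    p4050 = _tri_threshold(pat, lambda v: (v >= 40) & (v <= 50))

    out = pd.DataFrame(index=idx)
    out["winter_or_spring_birth"] = ws
    out["paternal_age_40_50"] = p4050
    out["any_childhood_adversity"] = _tri_any([profile[f] for f in adversity_set])
    return out
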