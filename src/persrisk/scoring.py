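"""Composite risk scores: the unweighted ERS, the weighted PERS with its
scaling and dose-response bands, and per-scheme scoring of whole cohorts.

Scores are defined for complete risk profiles only; profiles with missing
indicators must be imputed first (see :mod:`persrisk.impute`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .factors import FACTORS
from .schemes import WeightScheme, build_scheme

BAND_LABELS = ("<1", "1-2", "2-3", "3-4", ">=4")


def _as_profile_frame(profile) -> pd.DataFrame:
    if isinstance(profile, pd.Series):
        return profile.to_frame().T.astype(float)
    return profile


def _require_complete(values: pd.DataFrame, context: str) -> None:
    if values.isna().any().any():
        missing = values.columns[values.isna().any()].tolist()
        raise ValueError(
            f"cannot compute {context} on profiles with missing indicators "
            f"({missing}); impute the profile first"
        )


def score_ers(profile) -> pd.Series:
    """Unweighted environmental risk score: the count of present factors (0-14)."""
    profile = _as_profile_frame(profile)
    vals = profile[list(FACTORS)].astype(float)
    _require_complete(vals, "ERS")
    return vals.sum(axis=1)


def score_weighted(profile, scheme: WeightScheme) -> pd.Series:
    """Weighted composite score: sum of ``weights[f]`` over present factors
    plus ``absent_weights[f]`` over absent ones."""
    profile = _as_profile_frame(profile)
    missing_cols = [f for f in scheme.factors if f not in profile.columns]
    if missing_cols:
        raise ValueError(
            f"scheme {scheme.name!r} needs factors absent from the profile: {missing_cols}"
        )
    vals = profile[list(scheme.factors)].astype(float)
    _require_complete(vals, f"{scheme.name} score")
    total = pd.Series(0.0, index=vals.index)
    for f in scheme.factors:
        w, a = scheme.weights[f], scheme.absent_weight(f)
        total += vals[f] * w + (1.0 - vals[f]) * a
    return total


def scale_pers(pers_raw, scheme: WeightScheme, mode: str = "normalized"):
    """Rescale a raw weighted score for coefficient interpretability.

    ``normalized`` (default) maps the scheme maximum to its factor count:
    ``raw * k / sum(weights)``, so one unit of the scaled score corresponds to
    one average-weight factor.  ``literal`` multiplies by k outright.
    """
    if scheme.normalize_k is None:
        raise ValueError(f"scheme {scheme.name!r} has no scaling rule")
    if mode not in ("normalized", "literal"):
        raise ValueError(f"mode must be 'normalized' or 'literal', got {mode!r}")
    if mode == "literal":
        return pers_raw * scheme.normalize_k
    total = scheme.weight_sum
    if total == 0:
        raise ValueError("scheme weight sum is zero; cannot normalize")
    return pers_raw * scheme.normalize_k / total


def band_of(pers_raw, edges=(1, 2, 3, 4), allow_negative: bool = False):
    """Dose-response band of the raw (unscaled) weighted score.

    Bands are half-open: [0,1) -> "<1", [1,2) -> "1-2", [2,3) -> "2-3",
    [3,4) -> "3-4", [4,inf) -> ">=4"; the reference category is "<1".
    Negative scores are rejected unless ``allow_negative`` (schemes with
    negative absent-weights have no band definition).
    """
    arr = np.asarray(pers_raw, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("band_of requires finite scores")
    if not allow_negative and (arr < 0).any():
        raise ValueError("negative score has no dose-response band")
    edges = tuple(edges)
    labels = (f"<{edges[0]:g}",) + tuple(
        f"{a:g}-{b:g}" for a, b in zip(edges, edges[1:])
    ) + (f">={edges[-1]:g}",)
    bins = np.concatenate([[-np.inf], edges, [np.inf]])
    idx = np.digitize(arr, bins[1:-1], right=False)
    out = np.asarray(labels, dtype=object)[idx]
    if np.isscalar(pers_raw) or arr.ndim == 0:
        return out if isinstance(out, str) else out.item()
    if isinstance(pers_raw, pd.Series):
        return pd.Series(out, index=pers_raw.index)
    return out


def score_cohort(
    profile: pd.DataFrame,
    schemes=("updated_pers", "ers", "p_pers", "m_pers", "pers_no_smi"),
    scaling_mode: str = "normalized",
) -> pd.DataFrame:
    """Score a complete (imputed) risk profile under several schemes at once.

    Returns a DataFrame with one column per scheme (``<name>_score``) plus,
    for the updated PERS, ``ers``, ``pers_raw``, ``pers_scaled`` and ``band``.
    """
    out = pd.DataFrame(index=profile.index)
    for name in schemes:
        scheme = build_scheme(name) if isinstance(name, str) else name
        raw = score_weighted(profile, scheme)
        out[f"{scheme.name}_score"] = raw
        if scheme.name == "ers":
            out["ers"] = raw
        if scheme.name == "updated_pers":
            out["pers_raw"] = raw
            out["pers_scaled"] = scale_pers(raw, scheme, mode=scaling_mode)
            out["band"] = band_of(raw, edges=scheme.band_edges)
        if scheme.name == "pers_no_smi":
            out["pers_no_smi_scaled"] = raw * 14 / scheme.weight_sum
            out["pers_no_smi_band"] = band_of(raw)
    return out
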