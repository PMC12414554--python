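"""Weight schemes: the updated 14-factor PERS, the unweighted ERS, the two
historical comparator schemes (P-PERS, M-PERS) and the SMI-excluded variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .factors import FACTORS

SCHEME_NAMES = ("updated_pers", "ers", "p_pers", "m_pers", "pers_no_smi")


def log_weight(odds_ratio: float, ndigits: int | None = 3) -> float:
    """Natural-log weight of a meta-analytic odds ratio.

    Rounded to ``ndigits`` decimals (3 by default, matching how published
    schemes materialize weights from ORs); ``ndigits=None`` keeps full
    precision.
    """
    if not odds_ratio > 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    w = math.log(odds_ratio)
    return round(w, ndigits) if ndigits is not None else w


@dataclass(frozen=True)
class WeightScheme:
    """A named factor -> weight map with its scaling rule and band edges.

    ``weights[f]`` is added when factor ``f`` is present and
    ``absent_weights[f]`` (default 0) when it is absent.  ``normalize_k``
    gives the scaling rule ``score * k / sum(weights)`` (None = no scaling);
    ``band_edges`` are the cut points of the dose-response bands on the raw
    (unscaled) score, or None when bands are not defined for the scheme.
    """

    name: str
    weights: dict[str, float]
    absent_weights: dict[str, float] = field(default_factory=dict)
    normalize_k: int | None = None
    band_edges: tuple[float, ...] | None = None
    odds_ratios: dict[str, float] = field(default_factory=dict)

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(self.weights)

    @property
    def weight_sum(self) -> float:
        return sum(self.weights.values())

    def absent_weight(self, factor: str) -> float:
        return self.absent_weights.get(factor, 0.0)


def _load_catalog() -> dict:
    text = resources.files("persrisk.data").joinpath("schemes.yaml").read_text()
    return yaml.safe_load(text)


def build_scheme(name: str, full_precision: bool = False) -> WeightScheme:
    """Materialize a published weight scheme by name.

    Parameters
    ----------
    name
        One of ``updated_pers`` (14 log-odds weights, max 9.18, scaled to
        0-14, dose-response bands at 1/2/3/4), ``ers`` (unit weights),
        ``p_pers`` (8 log-odds weights), ``m_pers`` (6 integer-point factors,
        some absent states negative) or ``pers_no_smi`` (updated scheme with
        parental severe mental illness removed, max 7.81).
    full_precision
        For ``updated_pers``/``pers_no_smi``: recompute weights as unrounded
        ln(OR) instead of the published 3-decimal values.
    """
    if name not in SCHEME_NAMES:
        raise ValueError(f"unknown scheme {name!r}; valid schemes: {SCHEME_NAMES}")

    if name == "ers":
        return WeightScheme(name="ers", weights={f: 1.0 for f in FACTORS})

    catalog = _load_catalog()
    base = "updated_pers" if name == "pers_no_smi" else name
    entry = catalog[base]
    weights, absent, ors = {}, {}, {}
    for factor, spec in entry["factors"].items():
        if name == "pers_no_smi" and factor == "parental_smi":
            continue
        if "or" in spec and full_precision:
            weights[factor] = log_weight(spec["or"], ndigits=None)
        else:
            weights[factor] = float(spec["weight"])
        if "or" in spec:
            ors[factor] = float(spec["or"])
        if "absent_weight" in spec:
            absent[factor] = float(spec["absent_weight"])
    edges = entry.get("band_edges")
    return WeightScheme(
        name=name,
        weights=weights,
        absent_weights=absent,
        normalize_k=14 if entry.get("scaling") == "normalize_to_14" else None,
        band_edges=tuple(edges) if edges else None,
        odds_ratios=ors,
    )
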