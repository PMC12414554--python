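"""Outcome definitions: self-reported psychotic experiences (PE), clinician-rated
psychotic symptoms (PS), and the combined PE/PS group.

PE is flagged from the 16-item prodromal-questionnaire total at a cut-off of 6
(default rule ``gte``: total >= 6; ``gt`` is available because the boundary
case is genuinely ambiguous in common usage).  The combined PE/PS indicator is
the disjunction: positive if either observed outcome is positive; negative if
at least one outcome is observed negative and none positive (so a subject with
one missing outcome still contributes); missing only when both are missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PE_CUTOFF_DEFAULT = 6


def derive_outcomes(
    pe_total,
    ps_flag,
    cutoff: int = PE_CUTOFF_DEFAULT,
    pe_rule: str = "gte",
) -> pd.DataFrame:
    """Derive the tri-state outcome indicators from raw outcome measures.

    Parameters
    ----------
    pe_total
        Prodromal-questionnaire total score, integer in [0, 16] or missing.
    ps_flag
        Clinician-rated psychotic-symptom flag, {0, 1} or missing.
    cutoff
        PE threshold on the questionnaire total (default 6).
    pe_rule
        ``"gte"`` flags ``pe_total >= cutoff`` (default); ``"gt"`` flags
        strictly greater.

    Returns
    -------
    DataFrame with columns ``pe_flag``, ``ps_flag``, ``pe_or_ps`` in
    {1.0, 0.0, NaN}.
    """
    if not (0 <= cutoff <= 16):
        raise ValueError(f"PE cut-off must be within [0, 16], got {cutoff}")
    if pe_rule not in ("gte", "gt"):
        raise ValueError(f"pe_rule must be 'gte' or 'gt', got {pe_rule!r}")

    pe_total = pd.to_numeric(pd.Series(pe_total), errors="coerce")
    ps = pd.to_numeric(pd.Series(ps_flag), errors="coerce")
    ps.index = pe_total.index

    observed = pe_total.dropna()
    if ((observed < 0) | (observed > 16)).any():
        raise ValueError("pe_total outside [0, 16]")
    ps_obs = ps.dropna()
    if not ps_obs.isin([0, 1]).all():
        raise ValueError("ps_flag must be binary")

    pe_flag = pd.Series(np.nan, index=pe_total.index, dtype=float)
    ok = pe_total.notna()
    if pe_rule == "gte":
        pe_flag.loc[ok] = (pe_total[ok] >= cutoff).astype(float)
    else:
        pe_flag.loc[ok] = (pe_total[ok] > cutoff).astype(float)

    mat = pd.concat([pe_flag, ps], axis=1)
    pe_or_ps = pd.Series(np.nan, index=pe_total.index, dtype=float)
    pe_or_ps.loc[~mat.isna().all(axis=1)] = 0.0
    pe_or_ps.loc[(mat == 1).any(axis=1)] = 1.0

    return pd.DataFrame(
        {"pe_flag": pe_flag, "ps_flag": ps.astype(float), "pe_or_ps": pe_or_ps}
    )
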