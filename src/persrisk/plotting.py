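"""Plots for pooled dose-response results."""

from __future__ import annotations

import numpy as np


def plot_dose_response(results, outcome: str = "pe_or_ps", ax=None):
    """Pooled odds ratios per score band (reference band OR = 1) with 95% CIs
    on a log scale."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = results.table.query("outcome == @outcome and model == 'pers_bands'")
    if sub.empty:
        raise ValueError(f"no band model fitted for outcome {outcome!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))

    labels = ["<1 (ref)"] + [t.removeprefix("band_") for t in sub["term"]]
    ors = np.concatenate([[1.0], sub["OR"].to_numpy()])
    lo = np.concatenate([[1.0], sub["ci_low"].to_numpy()])
    hi = np.concatenate([[1.0], sub["ci_high"].to_numpy()])
    x = np.arange(len(labels))
    ax.errorbar(
        x, ors, yerr=[ors - lo, hi - ors], fmt="o", capsize=3, color="tab:blue"
    )
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yscale("log")
    ax.set_xticks(x, labels)
    ax.set_xlabel("PERS band")
    ax.set_ylabel("odds ratio (95% CI)")
    ax.set_title(f"Dose-response, outcome {outcome}")
    return ax
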