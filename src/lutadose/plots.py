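"""Bland-Altman scatter plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .compare import bland_altman, percent_difference


def bland_altman_plot(d_sm, d_rm, title: str = "", path: str | Path | None = None, ax=None):
    """Percent-difference Bland-Altman plot with bias and 1.96 SD limits.

    x-axis: pair mean dose; y-axis: percent difference (reference
    denominator).  Returns the matplotlib Axes.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d_sm = np.asarray(d_sm, float)
    d_rm = np.asarray(d_rm, float)
    res = bland_altman(d_sm, d_rm)
    diffs = percent_difference(d_sm, d_rm)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(0.5 * (d_sm + d_rm), diffs, s=14, alpha=0.6, edgecolors="none")
    ax.axhline(res.mean_bias_pct, color="green", lw=1.2,
               label=f"bias {res.mean_bias_pct:+.1f}%")
    for y in (res.loa_low_pct, res.loa_high_pct):
        ax.axhline(y, color="red", lw=1.0, ls="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference vs reference (%)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=120)
        plt.close(ax.figure)
    return ax
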