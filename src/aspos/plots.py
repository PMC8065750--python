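"""Diagnostic figures: Bland-Altman plot and the severity strip plot."""

from __future__ import annotations

import numpy as np

from .reliability import BlandAltmanResult


def bland_altman_plot(pairs, result: BlandAltmanResult, path=None, ax=None):
    """Mean-vs-difference plot with limits of agreement and trend line.

    ``pairs`` is the frame returned by ``select_rater_pair`` (columns
    ``total_a``, ``total_b``).  Saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(pairs["total_a"], dtype=float)
    b = np.asarray(pairs["total_b"], dtype=float)
    means = (a + b) / 2.0
    diffs = a - b
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=18, color="black", zorder=3)
    ax.axhline(result.mean_diff, color="tab:blue", label="mean difference")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="tab:red", linestyle="--", label=None)
    # regression of differences on means (descriptive trend only)
    if np.std(means) > 0:
        slope, intercept = np.polyfit(means, diffs, 1)
        xs = np.linspace(means.min(), means.max(), 50)
        ax.plot(xs, intercept + slope * xs, color="tab:red", linestyle=":", lw=1)
    ax.set_xlabel("mean of the two raters' totals")
    ax.set_ylabel("difference between totals")
    ax.set_title("Repeatability of the total score")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def threshold_strip_plot(totals, nihss, cutoff: int = 6, path=None, ax=None):
    """NIHSS by severity group with the severe-stroke cutoff line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .scale import SeverityGroup, severity_group

    totals = np.asarray(totals, dtype=int)
    nihss = np.asarray(nihss, dtype=float)
    labels = np.array([severity_group(t).value for t in totals])
    order = [g.value for g in SeverityGroup]
    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 4))
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for i, g in enumerate(order):
        vals = nihss[labels == g]
        if vals.size == 0:
            continue
        x = i + rng.uniform(-0.15, 0.15, size=vals.size)
        ax.scatter(x, vals, s=14, alpha=0.7)
    ax.axhline(cutoff, color="black", linestyle="--", lw=1, label=f"NIHSS = {cutoff}")
    ax.set_xticks(range(len(order)), order)
    ax.set_xlabel("ASPOS severity group")
    ax.set_ylabel("NIHSS")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
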