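"""Plots: heritability curves, re-ranking lines, window Manhattan, trajectories."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def heritability_curve(results, eg_grid, ax=None, label=None):
    """h^2(x) with a +-1 SE band along the gradient."""
    ax = ax or plt.subplots()[1]
    grid = np.asarray(eg_grid, dtype=float)
    h2, se = results.heritability_at(grid)
    ax.plot(grid, h2, label=label)
    if se is not None:
        ax.fill_between(grid, h2 - se, h2 + se, alpha=0.2)
    ax.set_xlabel("environmental gradient")
    ax.set_ylabel("heritability")
    return ax


def reranking_plot(results, sire_idx, eg_grid, classification=None, ax=None):
    """Sire gEBV trajectories across the gradient.

    With a :class:`~reactnorm.diagnostics.SireClassification`, resilient
    sires are drawn in red and sensitive sires in blue.
    """
    ax = ax or plt.subplots()[1]
    grid = np.asarray(eg_grid, dtype=float)
    for s in np.asarray(sire_idx):
        color, z = "0.8", 1
        if classification is not None:
            if s in classification.resilient:
                color, z = "tab:red", 3
            elif s in classification.sensitive:
                color, z = "tab:blue", 3
        ax.plot(grid, results.a0[s] + grid * results.a1[s], color=color, zorder=z, lw=1)
    ax.set_xlabel("environmental gradient")
    ax.set_ylabel("gEBV")
    return ax


def window_manhattan(scan, term="intercept", ax=None):
    """Per-window percentage of genetic variance, top threshold marked."""
    ax = ax or plt.subplots(figsize=(9, 3))[1]
    t = scan.table
    offset = 0
    ticks, labels = [], []
    for c, sub in t.groupby("chrom", sort=False):
        xs = np.arange(len(sub)) + offset
        ax.scatter(xs, sub[f"pct_{term}"], s=4)
        ticks.append(offset + len(sub) / 2)
        labels.append(str(c))
        offset += len(sub)
    flagged = t[t[f"top_{term}"]]
    if len(flagged):
        ax.axhline(flagged[f"pct_{term}"].min(), color="grey", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(f"% genetic variance ({term})")
    return ax


def trajectory_plot(clusters, ax=None):
    """Cluster mean +- SD of SNP-effect trajectories over the gradient."""
    ax = ax or plt.subplots()[1]
    for name, sub in clusters.summary.groupby("cluster"):
        ax.errorbar(sub["eg"], sub["mean"], yerr=sub["sd"], label=name, capsize=2)
    ax.set_xlabel("environmental gradient")
    ax.set_ylabel("SNP effect")
    ax.legend()
    return ax
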