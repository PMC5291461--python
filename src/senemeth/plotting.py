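"""Diagnostic plots: β scatter, subcategory rates, TSS-distance histograms,
and the sample-clustering dendrogram from uncentered-correlation distances."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
from scipy.cluster.hierarchy import dendrogram

from .expression import average_linkage


def beta_scatter(beta_x: pd.Series, beta_y: pd.Series, r2: float | None = None,
                 ax=None):
    """Scatter of per-probe β values between two samples (e.g. late vs early PDL)."""
    ax = ax or plt.gca()
    ax.scatter(beta_x, beta_y, s=2, alpha=0.3, rasterized=True)
    ax.set_xlabel(beta_x.name or "sample A")
    ax.set_ylabel(beta_y.name or "sample B")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    if r2 is not None:
        ax.annotate(f"$r^2$ = {r2:.3f}", xy=(0.05, 0.92), xycoords="axes fraction")
    return ax


def subcategory_rates(summary: pd.DataFrame, ax=None):
    """Bar chart of hyper/hypo rates per annotation subcategory."""
    ax = ax or plt.gca()
    summary[["hyper_rate", "hypo_rate"]].plot.bar(ax=ax, color=["crimson", "steelblue"])
    ax.set_ylabel("fraction of probes called")
    return ax


def distance_histogram(histogram: pd.DataFrame, ax=None):
    """Stacked per-promoter-class histogram of probe-to-TSS distances."""
    ax = ax or plt.gca()
    histogram.plot.bar(ax=ax, stacked=True, width=1.0)
    ax.set_ylabel("CpG probes")
    ax.set_xlabel("distance to nearest TSS (bp)")
    return ax


def sample_dendrogram(dist: pd.DataFrame, ax=None):
    """Average-linkage dendrogram over an uncentered-correlation distance matrix."""
    ax = ax or plt.gca()
    dendrogram(average_linkage(dist), labels=list(dist.columns), ax=ax)
    ax.set_ylabel("1 - uncentered correlation")
    return ax
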