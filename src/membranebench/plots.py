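"""Minimal diagnostic plots (matplotlib) for the pipeline's main outputs."""

from __future__ import annotations

import numpy as np


def gravy_histograms(profiles, ax=None):
    """Overlapping weighted GRAVY histograms, one per workflow profile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for prof in profiles:
        centers = 0.5 * (prof.histogram_edges[:-1] + prof.histogram_edges[1:])
        weights = prof.histogram_weighted
        total = weights.sum()
        ax.step(centers, weights / total if total else weights, where="mid",
                label=f"{prof.workflow} (median {prof.weighted_median:.2f})")
    ax.set_xlabel("GRAVY score")
    ax.set_ylabel("weighted fraction")
    ax.legend(fontsize=7)
    return ax


def pca_scatter(profiles, design=None, ax=None):
    """Scatter of sample coordinates on the first two components."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    coords = profiles.coordinates
    for sid, row in coords.iterrows():
        ax.scatter(row.iloc[0], row.iloc[1] if coords.shape[1] > 1 else 0.0, s=16)
        ax.annotate(str(sid), (row.iloc[0], row.iloc[1] if coords.shape[1] > 1 else 0.0),
                    fontsize=6)
    evr = profiles.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    return ax


def precision_bars(results, ax=None):
    """Average fold-change SD per workflow, IMPs vs soluble proteins."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    names = [r.workflow for r in results]
    x = np.arange(len(names))
    ax.bar(x - 0.2, [r.avg_sd_imp for r in results], width=0.4, label="IMPs")
    ax.bar(x + 0.2, [r.avg_sd_sol for r in results], width=0.4, label="Sols")
    ax.set_xticks(x, names, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("average SD of log2 FC")
    ax.legend()
    return ax
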