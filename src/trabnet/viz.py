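"""Thin plotting helpers over precomputed counts (requires matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_rose(counts, ax=None, **bar_kwargs):
    """Rose diagram of azimuth sector counts (equal-width sectors).

    ``counts`` as produced by :func:`trabnet.stats.rose_bins`.  Returns the
    polar axes.  The diagram has no preferred orientation relative to the
    specimen; it only shows whether the azimuth distribution is uniform or
    directional.
    """
    import matplotlib.pyplot as plt
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    width = 2 * np.pi / n
    theta = np.arange(n) * width + width / 2
    ax.bar(theta, counts, width=width, bottom=0.0,
           **{"edgecolor": "black", "linewidth": 0.5, **bar_kwargs})
    return ax


def plot_histogram(counts, edges, ax=None, xlabel="", **bar_kwargs):
    """Bar plot of precomputed histogram counts (e.g. theta or ITA)."""
    import matplotlib.pyplot as plt
    counts = np.asarray(counts, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           **{"edgecolor": "black", "linewidth": 0.5, **bar_kwargs})
    ax.set_xlabel(xlabel)
    ax.set_ylabel("count")
    return ax
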