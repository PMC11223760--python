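"""Plot helpers for traces and size distributions (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_size_distribution(diameters_nm, ax=None, bins=40, label=None):
    """Histogram + KDE of event diameters; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt
    from scipy import stats

    d = np.asarray(diameters_nm, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.hist(d, bins=bins, density=True, alpha=0.4, label=label)
    if d.size >= 10 and np.ptp(d) > 0:
        grid = np.linspace(0, 1.2 * d.max(), 512)
        ax.plot(grid, stats.gaussian_kde(d)(grid))
    if d.size:
        ax.axvline(float(np.mean(d)), linestyle="--")
    ax.set_xlabel("diameter (nm)")
    ax.set_ylabel("density")
    return ax


def plot_trace(trace, ax=None, max_dwells=50_000):
    """Plot the first ``max_dwells`` dwells of a trace."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    n = min(len(trace), max_dwells)
    t = np.arange(n) * trace.dwell_time
    ax.plot(t, trace.counts[:n], linewidth=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("counts per dwell")
    return ax
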