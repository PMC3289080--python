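"""Plot hooks: fold-change distributions and suppression bands.

Thin matplotlib wrappers; each function draws onto a provided or fresh Axes
and returns it, so figures compose and tests can run headless.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .suppression_analysis import NullDistribution  # noqa: E402


def plot_null_distributions(nulls: list[NullDistribution], ax=None, bins=30):
    """Overlaid histograms of log10 fold-change distributions (density scale)."""
    if ax is None:
        _, ax = plt.subplots()
    for null in nulls:
        label = null.kind
        if null.intensity_level is not None:
            label += f" @ {null.intensity_level:.3g}"
        ax.hist(null.log_ratios, bins=bins, density=True, alpha=0.5, label=label)
    ax.set_xlabel("log10 fold change")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def plot_suppression_band(stats: pd.DataFrame, ax=None):
    """Mean suppression ratio with ±SD and ±3·SD bands versus intensity level."""
    if ax is None:
        _, ax = plt.subplots()
    level = stats["level"].to_numpy()
    mean = stats["mean_ratio"].to_numpy()
    sd = stats["sd"].to_numpy()
    ax.plot(level, mean, "k-", label="mean suppression ratio")
    ax.plot(level, mean - sd, "-", color="gray", lw=1)
    ax.plot(level, mean + sd, "-", color="gray", lw=1, label="mean ± SD")
    ax.plot(level, np.clip(mean - 3 * sd, 0, None), "--", color="gray", lw=1)
    ax.plot(level, mean + 3 * sd, "--", color="gray", lw=1, label="mean ± 3 SD")
    ax.set_xscale("log")
    ax.set_xlabel("intensity level (ion counts)")
    ax.set_ylabel("observed/true area ratio")
    ax.legend()
    return ax


def plot_correction_functions(functions, ax=None, n_points=200):
    """Library of correction functions in log-log space (observed vs true)."""
    if ax is None:
        _, ax = plt.subplots()
    for f in functions:
        lo, hi = f.valid_range
        y = np.logspace(np.log10(lo), np.log10(hi), n_points)
        ax.plot(np.log10(y), np.log10(f(y)), alpha=0.6)
    ax.set_xlabel("log10 observed intensity")
    ax.set_ylabel("log10 corrected intensity")
    return ax
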