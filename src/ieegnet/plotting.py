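"""Minimal diagnostic plots (matplotlib)."""

from __future__ import annotations

import numpy as np

from .spatial import BaselineFit, evaluate_baseline


def plot_baseline(distances_mm, correlations, fit: BaselineFit, ax=None):
    """Scatter of the fitting pool with the fitted decay curve overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    d = np.asarray(distances_mm, dtype=float)
    ax.plot(d, np.asarray(correlations, dtype=float), ".", ms=2, alpha=0.3, label="pairs")
    grid = np.linspace(max(d.min(), 1e-6), d.max(), 200)
    ax.plot(grid, evaluate_baseline(fit, grid), "r-", lw=2, label="rat11 baseline")
    ax.set_xlabel("Euclidean distance (mm)")
    ax.set_ylabel("correlation")
    ax.legend()
    return ax


def plot_coverage_scan(scan, ax=None):
    """AUC with CI band over the minimum-coverage threshold n_x."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    defined = scan[scan["defined"]]
    ax.plot(defined["n_x"], defined["auc"], "b-", label="AUC")
    ax.fill_between(defined["n_x"], defined["ci_low"], defined["ci_high"], alpha=0.2)
    ax.axhline(0.5, color="gray", ls=":")
    ax.set_xlabel("minimum contacts per compartment (n_x)")
    ax.set_ylabel("AUC (poor vs good outcome)")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
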