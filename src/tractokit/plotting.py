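"""Plot helpers for along-tract analyses (raw profiles, betas, -log10 p)."""

from __future__ import annotations

from typing import Dict

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np               # noqa: E402
import pandas as pd              # noqa: E402

from .formats.tables import ARCLENGTH_COLUMN   # noqa: E402
from .stats import StatResult                  # noqa: E402


def plot_profiles(profiles: pd.DataFrame, ax=None, atlas_column="atlas"):
    """Raw subject curves (green) with the atlas reference (blue) if present."""
    if ax is None:
        _, ax = plt.subplots()
    grid = profiles[ARCLENGTH_COLUMN]
    for c in profiles.columns:
        if c in (ARCLENGTH_COLUMN, atlas_column):
            continue
        ax.plot(grid, profiles[c], color="seagreen", alpha=0.6, lw=1)
    if atlas_column in profiles.columns:
        ax.plot(grid, profiles[atlas_column], color="royalblue", lw=2,
                label="atlas")
        ax.legend()
    ax.set_xlabel("arclength (mm)")
    return ax


def plot_local_pvalues(results: Dict[str, StatResult], ax=None, q=0.05):
    """FDR-corrected -log10 p along the tract, one curve per covariate."""
    if ax is None:
        _, ax = plt.subplots()
    for name, res in results.items():
        with np.errstate(divide="ignore"):
            y = -np.log10(res.p_fdr)
        ax.plot(res.grid, y, label=name)
        sig = res.significant
        ax.plot(res.grid[sig], y[sig], "o", ms=4)
    ax.axhline(-np.log10(q), ls="--", color="gray", lw=0.8)
    ax.set_xlabel("arclength (mm)")
    ax.set_ylabel("-log10 corrected p")
    ax.legend()
    return ax


def plot_betas(results: Dict[str, StatResult], ax=None):
    """Coefficient curves with significant bins marked by filled circles."""
    if ax is None:
        _, ax = plt.subplots()
    for name, res in results.items():
        line, = ax.plot(res.grid, res.beta, label=name)
        ax.fill_between(res.grid, res.beta - 1.96 * res.se,
                        res.beta + 1.96 * res.se, alpha=0.15,
                        color=line.get_color())
        sig = res.significant
        ax.plot(res.grid[sig], res.beta[sig], "o", ms=4,
                color=line.get_color())
    ax.axhline(0, color="gray", lw=0.8)
    ax.set_xlabel("arclength (mm)")
    ax.set_ylabel("beta")
    ax.legend()
    return ax
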