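"""Plot helpers: trajectories, shift profiles, effect-size scatter."""
from __future__ import annotations

import numpy as np

from .dataset import ExpressionDataset
from .trajectory import PolyFitResult, _overlap_grid, fit_best_polynomial

__all__ = ["plot_gene_trajectories", "plot_shift_profile",
           "plot_effect_scatter"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_gene_trajectories(ds: ExpressionDataset, gene, max_degree: int = 3,
                           ax=None):
    """Scatter both groups' expression against age with their fitted curves."""
    ax = _axes(ax)
    aa, ya, ab, yb = ds.group_arrays(gene)
    a_level, b_level = ds.group_levels
    for ages, values, label, color in ((aa, ya, a_level, "tab:red"),
                                       (ab, yb, b_level, "tab:green")):
        fit = fit_best_polynomial(ages, values, max_degree=max_degree)
        grid = np.linspace(ages.min(), ages.max(), 100)
        ax.scatter(ages, values, s=16, color=color, alpha=0.7, label=label)
        ax.plot(grid, fit.predict(grid), color=color)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("expression")
    ax.set_title(str(gene))
    ax.legend()
    return ax


def plot_shift_profile(shift_estimate, ax=None):
    """Per-grid-point time shifts along the alignment path."""
    ax = _axes(ax)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.plot(shift_estimate.query_ages, shift_estimate.shifts, marker="o",
            ms=3)
    ax.axhline(shift_estimate.mean_shift, ls="--", color="tab:blue",
               label=f"mean shift {shift_estimate.mean_shift:.1f} y")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("time shift (years)")
    ax.legend()
    return ax


def plot_effect_scatter(age_corr, effect, ax=None):
    """Case/control effect size against expression-age correlation, with
    the OLS line whose residuals define the corrected effect."""
    ax = _axes(ax)
    x = np.asarray(age_corr, dtype=float)
    y = np.asarray(effect, dtype=float)
    ax.scatter(x, y, s=6, alpha=0.4)
    beta = np.polyfit(x, y, 1)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, np.polyval(beta, grid), color="tab:red")
    ax.set_xlabel("expression-age correlation r")
    ax.set_ylabel("effect size (Cohen's d)")
    return ax
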