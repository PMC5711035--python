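"""Matplotlib hooks for the standard views of encoded and simulated data.

Each function draws on (and returns) an Axes so figures compose freely.
Simulation time is in iterations; an optional ``minutes_per_step`` rescale is
provided purely for visual alignment with experimental time courses and is
never used in any computation.
"""

from __future__ import annotations

import numpy as np

from .expression import ExpressionMatrix
from .patterns import AttractorSet
from .population import PopulationTrace, StateDistribution, pc_projection

__all__ = [
    "plot_phase_heatmap",
    "plot_mean_expression",
    "plot_occupancy",
    "plot_pc_scatter",
]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_phase_heatmap(matrix: ExpressionMatrix, order: np.ndarray | None = None, ax=None):
    """Gene x time heat map, rows optionally sorted by fitted phase."""
    ax = _get_ax(ax)
    values = matrix.values if order is None else matrix.values[order]
    rows = (values - values.mean(axis=1, keepdims=True)) / (
        values.std(axis=1, keepdims=True) + 1e-12
    )
    ax.imshow(rows, aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax.set_xlabel("time point")
    ax.set_ylabel("gene (sorted by phase)" if order is not None else "gene")
    return ax


def plot_mean_expression(trace: PopulationTrace, gene: int, minutes_per_step: float | None = None, ax=None):
    """Population-averaged expression of one gene versus time."""
    from .population import population_mean_expression

    ax = _get_ax(ax)
    series = population_mean_expression(trace, gene)
    t = np.arange(series.size)
    if minutes_per_step is not None:
        t = t * minutes_per_step
        ax.set_xlabel("time (min, display rescale only)")
    else:
        ax.set_xlabel("iteration")
    ax.plot(t, series)
    ax.set_ylabel("<sigma_i(t)>_K")
    ax.set_ylim(-1.05, 1.05)
    return ax


def plot_occupancy(dist: StateDistribution, ax=None):
    """Stacked occupancy P_mu(t) of the attractor states."""
    ax = _get_ax(ax)
    p, n_t = dist.P.shape
    ax.stackplot(np.arange(n_t), dist.P, labels=[f"state {mu}" for mu in range(p)])
    ax.set_xlabel("iteration")
    ax.set_ylabel("P_mu(t)")
    ax.set_ylim(0, 1)
    ax.legend(fontsize="x-small", ncol=2)
    return ax


def plot_pc_scatter(points: np.ndarray, attractors: AttractorSet, states: np.ndarray | None = None, ax=None):
    """Cells and attractors in the attractor principal-component plane."""
    ax = _get_ax(ax)
    coords, attr_coords = pc_projection(points, attractors)
    ax.scatter(coords[:, 0], coords[:, 1], c=states, cmap="hsv", s=8)
    ax.scatter(attr_coords[:, 0], attr_coords[:, 1], marker="*", s=200,
               c=np.arange(attractors.p), cmap="hsv", edgecolors="k")
    for mu, (x, y) in enumerate(attr_coords):
        ax.annotate(str(mu), (x, y))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    return ax
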