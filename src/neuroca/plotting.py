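"""Small matplotlib helpers for the standard diagnostic figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .activation import ActivationParams, evaluate
from .analysis import BifurcationResult, CobwebTrace

__all__ = ["plot_mean_activity", "plot_cobweb", "plot_bifurcation"]


def plot_mean_activity(series, ax=None, **kw):
    """Lattice-mean activity versus timestep."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.arange(len(series)), series, **kw)
    ax.set_xlabel("timestep")
    ax.set_ylabel(r"$\langle a \rangle$")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_cobweb(trace: CobwebTrace, p: ActivationParams, ax=None):
    """Cobweb trace over the activation curve and the identity line."""
    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(0.0, 1.0, 512)
    ax.plot(grid, evaluate(grid, p), "k-", lw=1.5, label="activation")
    ax.plot(grid, grid, "k--", lw=1, label=r"$a_{out} = a_{in}$")
    ax.plot(trace.points[:, 0], trace.points[:, 1], "r-", lw=0.8)
    ax.plot([trace.start], [0.0], "b*", ms=10)
    ax.set_xlabel(r"$a_{in}$")
    ax.set_ylabel(r"$a_{out}$")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_bifurcation(result: BifurcationResult, ax=None, **kw):
    """Steady-regime lattice means against the swept a2."""
    if ax is None:
        _, ax = plt.subplots()
    for a2, vals in zip(result.a2_values, result.steady_values):
        vals = np.asarray(vals).ravel()
        ax.plot(np.full(vals.size, a2), vals, "k.", ms=2, **kw)
    ax.set_xlabel(r"$a_2$")
    ax.set_ylabel("steady-regime values")
    return ax
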