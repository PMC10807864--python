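"""Quick-look figures for simulations and sweeps (matplotlib)."""

from __future__ import annotations

import numpy as np

from .simulator import Trajectory, delay_rates, persistent_areas

__all__ = ["plot_trajectory", "plot_delay_profile", "plot_sweep_heatmap"]


def plot_trajectory(traj: Trajectory, areas=None, population: str = "A", ax=None):
    """Firing-rate time courses of selected areas (default: six spread by name)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    names = traj.names
    if areas is None:
        areas = [names[i] for i in
                 np.linspace(0, len(names) - 1, min(6, len(names)), dtype=int)]
    for area in areas:
        ax.plot(traj.t, traj.r[population][:, names.index(area)], label=area)
    ax.axvspan(traj.protocol.T_on, traj.protocol.T_off, color="0.9",
               label="stimulus")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"rate of population {population} (Hz)")
    ax.legend(fontsize="small", ncol=2)
    return ax


def plot_delay_profile(traj: Trajectory, covariate, covariate_label: str = "hierarchy",
                       theta: float = 5.0, ax=None):
    """Delay rate vs an area covariate, persistent areas highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    rates = delay_rates(traj)
    pers = persistent_areas(rates, theta)
    covariate = np.asarray(covariate, float)
    ax.scatter(covariate[~pers], rates[~pers], c="0.6", label="transient")
    ax.scatter(covariate[pers], rates[pers], c="tab:red", label="persistent")
    ax.axhline(theta, ls="--", c="k", lw=0.8)
    ax.set_xlabel(covariate_label)
    ax.set_ylabel("delay rate (Hz)")
    ax.legend(fontsize="small")
    return ax


def plot_sweep_heatmap(counts, g_EI0_grid, scaling_grid, stable_mask=None, ax=None):
    """Persistent-area counts over the local-inhibition grid; unstable cells hatched."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    counts = np.asarray(counts)
    im = ax.imshow(counts, origin="lower", aspect="auto", cmap="viridis",
                   extent=[min(scaling_grid), max(scaling_grid),
                           min(g_EI0_grid), max(g_EI0_grid)])
    if stable_mask is not None:
        unstable = ~np.asarray(stable_mask, bool)
        ys, xs = np.nonzero(unstable)
        for i, j in zip(ys, xs):
            ax.plot(scaling_grid[j], g_EI0_grid[i], "x", c="w", ms=8)
    ax.figure.colorbar(im, ax=ax, label="persistent areas")
    ax.set_xlabel("g_EI scaling")
    ax.set_ylabel("g_EI,0 (nA)")
    return ax
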