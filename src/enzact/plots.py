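"""Matplotlib views of the core artifacts (all optional; nothing here is
required by the analysis code)."""

from __future__ import annotations

import numpy as np

from .optimality import ActivityGrid, VolcanoCurve


def plot_activity_grid(grid: ActivityGrid, ax=None, log_color: bool = True):
    """Heat map of activity over (dG1, dGT) with the ridge overlaid."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    if ax is None:
        _, ax = plt.subplots()
    v = np.where(grid.v > 0, grid.v, np.nan)
    norm = LogNorm(vmin=np.nanmin(v), vmax=np.nanmax(v)) if log_color else None
    mesh = ax.pcolormesh(grid.dG1_values, grid.dGT_values, v, norm=norm, shading="auto")
    ax.plot(grid.ridge_dG1, grid.dGT_values, "k--", lw=1, label="ridge")
    ax.set_xlabel(r"$\Delta G_1$ (kJ/mol)")
    ax.set_ylabel(r"$\Delta G_T$ (kJ/mol)")
    ax.figure.colorbar(mesh, ax=ax, label=r"$v$ ($\mu$M/s)")
    ax.legend(loc="upper left")
    return ax


def plot_volcano(curve: VolcanoCurve, ax=None, **kwargs):
    """v against Km on log-log axes, apex marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(curve.Km, curve.v, **kwargs)
    ax.axvline(curve.apex_Km, ls="--", color="gray", lw=1)
    ax.set_xlabel(r"$K_m$ ($\mu$M)")
    ax.set_ylabel(r"$v$ ($\mu$M/s)")
    return ax


def plot_log_ratio_histograms(results, ax=None, bin_width: float | None = None):
    """Per-category histograms of log10(Km/[S]) with fitted Gaussians."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    bw = bin_width or results.bin_width
    df = results.to_frame()
    colors = {"major_metabolite": "tab:red", "cofactor": "tab:blue", "ATP": "k"}
    for stats in results.category_stats:
        if stats.n_entries == 0:
            continue
        x = df.loc[df["category"] == stats.label, "log10_Km_over_S"].to_numpy()
        bins = np.arange(np.floor(x.min() / bw) * bw, x.max() + bw, bw)
        ax.hist(x, bins=bins, histtype="step", color=colors.get(stats.label),
                label=f"{stats.label} (n={stats.n_entries})")
        if stats.fit is not None:
            xs = np.linspace(bins[0], bins[-1], 200)
            ax.plot(xs, stats.fit.amplitude
                    * np.exp(-((xs - stats.fit.mu) ** 2) / (2 * stats.fit.sigma**2)),
                    color=colors.get(stats.label), lw=1, alpha=0.7)
    ax.set_xlabel(r"$\log_{10}(K_m/[\mathrm{S}])$")
    ax.set_ylabel("entries per bin")
    ax.legend()
    return ax
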