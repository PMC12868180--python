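"""Optional figure helpers for curves and boundaries (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_metric_curves", "plot_boundary"]


def plot_metric_curves(curves: pd.DataFrame, path) -> None:
    """Grid of metric-vs-nPat panels, one line per stimulation count."""
    metrics = list(curves["metric"].unique())
    methods = list(curves["method"].unique())
    fig, axes = plt.subplots(
        len(metrics), len(methods),
        figsize=(4 * len(methods), 3 * len(metrics)),
        squeeze=False, sharex=True,
    )
    for i, metric in enumerate(metrics):
        for j, method in enumerate(methods):
            ax = axes[i][j]
            sub = curves[(curves["metric"] == metric) & (curves["method"] == method)]
            for n_stim, g in sub.groupby("n_stim"):
                g = g.sort_values("n_pat")
                ax.plot(g["n_pat"], g["mean"], marker="o", ms=3, label=f"{n_stim}Stim")
            if i == 0:
                ax.set_title(method)
            if j == 0:
                ax.set_ylabel(f"{metric} [%]")
            if i == len(metrics) - 1:
                ax.set_xlabel("nPat")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_boundary(boundary: pd.DataFrame, path, observed_n_pat=None, observed_n_stim=None) -> None:
    """Mean minimum-nStim boundary with 95% credible band per method."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for method, g in boundary.groupby("method"):
        g = g.sort_values("n_pat")
        ax.plot(g["n_pat"], g["mean"], label=method)
        ax.fill_between(g["n_pat"], g["ci_low"], g["ci_high"], alpha=0.2)
    if observed_n_pat and observed_n_stim:
        ax.axvspan(0, observed_n_pat, ymax=0.0, color="none")
        ax.add_patch(
            plt.Rectangle((0, 0), observed_n_pat, observed_n_stim,
                          alpha=0.15, color="gold", label="observed data region")
        )
    ax.set_xlabel("nPat")
    ax.set_ylabel("minimum nStim for stability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
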