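"""Optional figure helpers for the ensemble experiments.

Each function takes the tidy DataFrame produced by the corresponding
experiment and draws a matplotlib figure mirroring the standard layouts:
alignment curves vs n_d, time courses, hub-targeting bar profiles, and
overlaid spectrum histograms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_alignment(summary: pd.DataFrame, out: str | None = None):
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for (n, variant), grp in summary.groupby(["n", "b_variant"]):
        grp = grp.sort_values("n_d")
        ax.errorbar(
            grp["n_d"], grp["mean_cos_full"], yerr=grp["std_cos_full"],
            marker="o", capsize=3, label=f"n={n} ({variant} B)",
        )
    ax.set_xlabel(r"driver count $n_d$")
    ax.set_ylabel(r"$\mu_{\cos\theta}(x_{ref}, v_{max})$")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
    return fig


def plot_time_course(df: pd.DataFrame, out: str | None = None):
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    agg = df.groupby(["n_d", "t"], as_index=False)["cos_full"].mean()
    for n_d, grp in agg.groupby("n_d"):
        ax.plot(grp["t"], grp["cos_full"], marker="o", label=f"$n_d$={n_d}")
    ax.set_xlabel("evaluation time $t$")
    ax.set_ylabel(r"mean $\cos\theta(x_{ref}, v_{max})$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
    return fig


def plot_hub_profile(summary: pd.DataFrame, out: str | None = None):
    plt = _plt()
    conditions = summary.groupby(["n", "n_d"])
    fig, axes = plt.subplots(
        1, len(conditions), figsize=(3.2 * len(conditions), 3), squeeze=False
    )
    for ax, ((n, n_d), grp) in zip(axes[0], conditions):
        grp = grp.sort_values("bin")
        ax.bar(grp["percentile"], grp["mu"], width=4.0)
        ax.set_title(f"n={n}, $n_d$={n_d}", fontsize=9)
        ax.set_xlabel("degree percentile (top first)")
    axes[0][0].set_ylabel(r"mean squared $u_{ref}$ entry $\mu_i$")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
    return fig


def plot_spectra(info, gram, out: str | None = None):
    """Overlay log-eigenvalue histograms of the information and gramian
    spectra (different dimensions; shown side by side, never pooled)."""
    plt = _plt()
    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    for ax, ens, title in ((axes[0], info, "information spectrum ($S_u$)"),
                           (axes[1], gram, "gramian spectrum ($W(\\infty)$)")):
        positive = ens.samples[ens.samples > 0]
        ax.hist(np.log10(positive), bins="fd", density=True)
        ax.set_xlabel(r"$\log_{10}\lambda$")
        ax.set_title(title, fontsize=9)
    axes[0].set_ylabel("density")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
    return fig
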