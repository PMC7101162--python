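"""Matplotlib exports: trace plots and recovery scatter plots."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

_CHAIN_COLORS = ("tab:blue", "tab:green", "tab:red")


def plot_trace(results, path=None):
    """Per-parameter trace plot, one coloured line per chain."""
    draws = results.draws
    k = draws.k
    fig, axes = plt.subplots(k, 2, figsize=(9, 2.2 * k), squeeze=False)
    labels = results.component_labels()
    for j in range(k):
        for name, col, arr in (("mu", 0, draws.mu), ("sigma", 1, draws.sigma)):
            ax = axes[j][col]
            for c in range(draws.chains):
                ax.plot(arr[c, :, j], lw=0.4,
                        color=_CHAIN_COLORS[c % len(_CHAIN_COLORS)])
            ax.set_ylabel(f"{name} [{labels[j]}]", fontsize=8)
    axes[-1][0].set_xlabel("retained draw")
    axes[-1][1].set_xlabel("retained draw")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_recovery(records: Sequence, path=None):
    """True vs estimated mean thickness with 68% credible error bars."""
    groups = sorted({r.group for r in records})
    cmap = plt.get_cmap("tab10")
    fig, (ax_mu, ax_sd) = plt.subplots(1, 2, figsize=(9, 4))
    for gi, g in enumerate(groups):
        sub = [r for r in records if r.group == g]
        truth = [r.true_mean for r in sub]
        est = [r.estimated_median for r in sub]
        yerr = np.array([[r.estimated_median - r.lo for r in sub],
                         [r.hi - r.estimated_median for r in sub]])
        ax_mu.errorbar(truth, est, yerr=yerr, fmt="o", ms=4,
                       color=cmap(gi % 10), label=f"group {g}", lw=0.8)
        sd_t = [r.true_sd for r in sub]
        sd_e = [r.sd_median for r in sub]
        sd_err = np.array([[r.sd_median - r.sd_lo for r in sub],
                           [r.sd_hi - r.sd_median for r in sub]])
        ax_sd.errorbar(sd_t, sd_e, yerr=sd_err, fmt="o", ms=4,
                       color=cmap(gi % 10), lw=0.8)
    for ax, what in ((ax_mu, "mean thickness"), (ax_sd, "standard deviation")):
        lims = ax.get_xlim()
        ax.plot(lims, lims, "k--", lw=0.6)
        ax.set_xlabel(f"true {what}")
        ax.set_ylabel(f"estimated {what}")
    ax_mu.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
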