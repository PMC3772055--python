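"""Plot helpers for branches, two-parameter regions and fraction panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_branches", "plot_region", "plot_fractions"]


def plot_branches(frame, parameter, observables, path=None, title=None):
    """Forward/backward branch traces (solid stable, dotted unstable)."""
    fig, axes = plt.subplots(1, len(observables),
                             figsize=(4 * len(observables), 3.2), squeeze=False)
    for ax, obs in zip(axes[0], observables):
        for direction, style in (("forward", "C0"), ("backward", "C3")):
            sub = frame[frame["direction"] == direction]
            ax.plot(sub[parameter], sub[obs], color=style, lw=1.5,
                    label=direction)
        ax.set_xlabel(parameter)
        ax.set_ylabel(obs)
    axes[0][0].legend(frameon=False, fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_region(region, path=None):
    """Saddle-node loci bounding the bistable region in the parameter plane."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    b = region.boundary
    if len(b):
        ax.plot(b["lo"], b["p2"], "C0.-", label="lower fold")
        ax.plot(b["hi"], b["p2"], "C3.-", label="upper fold")
        ax.fill_betweenx(b["p2"], b["lo"], b["hi"], alpha=0.15, color="C0")
    ax.set_xlabel(region.p1)
    ax.set_ylabel(region.p2)
    ax.set_yscale("log")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_fractions(frame, path=None):
    """Grouped bars of the four phenotype fractions per genotype."""
    obs = ["pleC_kinase_fraction", "divKp_fraction", "ctrAp_fraction",
           "pleDp_fraction"]
    genotypes = frame["genotype"].tolist()
    x = np.arange(len(genotypes))
    width = 0.2
    fig, ax = plt.subplots(figsize=(1.6 * len(genotypes) + 2, 3.2))
    for i, ob in enumerate(obs):
        ax.bar(x + (i - 1.5) * width, frame[ob], width, label=ob)
    ax.set_xticks(x)
    ax.set_xticklabels(genotypes, rotation=20, ha="right", fontsize=8)
    ax.set_ylabel("steady-state fraction")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
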