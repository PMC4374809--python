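"""Figure-style views of profiles, ratio curves and IP folds."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .clustering import RatioCurve
from .profiles import PositionalProfile
from .reference import TransgeneConstruct

_ROLE_COLORS = {"coding": "#2ca02c", "normalizer": "#999999",
                "target_site": "#1f3a93", "utr": "#9ecae1",
                "linker": "#555555"}


def plot_profiles(profiles_by_name: Mapping[str, PositionalProfile],
                  construct: TransgeneConstruct | None = None,
                  path: str | Path | None = None):
    """Stacked per-genotype antisense profiles with the construct schematic."""
    n = len(profiles_by_name)
    fig, axes = plt.subplots(n, 1, figsize=(8, 1.6 * n + 1), sharex=True,
                             squeeze=False)
    for ax, (name, prof) in zip(axes[:, 0], profiles_by_name.items()):
        ax.fill_between(range(prof.length), prof.values, step="mid", lw=0)
        ax.set_ylabel(name, rotation=0, ha="right", fontsize=8)
        if construct is not None:
            for seg in construct.segments:
                s, e = construct.segment_interval(seg.name)
                ax.axvspan(s, e, color=_ROLE_COLORS[seg.role], alpha=0.12)
    axes[-1, 0].set_xlabel("nt from start codon")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_ratio_curves(curves: Sequence[RatioCurve],
                      path: str | Path | None = None):
    """Per-cluster log2(mutant / wild type) along the binned gene body."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        ax.plot(range(1, len(c.values) + 1), c.values,
                marker="o", ms=3, label=f"cluster {c.cluster_id} (n={c.n_genes})")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("bin (5' to 3')")
    ax.set_ylabel("log2 mutant / wild type")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_ip_folds(folds: Mapping[str, float], path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(5, 3))
    names = list(folds)
    ax.bar(names, [folds[k] for k in names])
    ax.axhline(1.0, color="k", lw=0.5)
    ax.set_ylabel("IP / control fold")
    ax.tick_params(axis="x", labelrotation=30)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
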