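"""Optional rendering of metaprofiles and proportional-gene plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import annotation
from .profiles import MetaProfile


def plot_metaprofile(profile: MetaProfile, path: str | Path, title: str = "") -> None:
    """Histogram of slot means with 95% CI bars, exons vs introns coloured."""
    slots = profile.slots
    x = np.arange(len(slots))
    colors = [
        "#c44e52" if f == annotation.CANONICAL else "#4c72b0"
        for f in slots["feature"]
    ]
    fig, ax = plt.subplots(figsize=(9, 3.5))
    ax.bar(x, slots["mean"], yerr=slots["ci95"], color=colors, capsize=2)
    ax.set_xticks(x)
    ax.set_xticklabels(slots["slot"], rotation=90, fontsize=7)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("mean Z")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_gene_percent_profile(
    profile: pd.DataFrame, path: str | Path, title: str = ""
) -> None:
    """Mean Z over proportional gene coordinates (flank - gene - flank)."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    mid = (profile["bin_lo"] + profile["bin_hi"]) / 2
    ax.plot(mid, profile["mean"], lw=1.2)
    ax.axvspan(0, 100, color="0.9", zorder=0)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("gene position (%)")
    ax.set_ylabel("mean Z")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
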