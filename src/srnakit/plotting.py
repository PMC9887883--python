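"""Plot export: differential scatter and metagene line charts."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .types import DifferentialResult, MetageneProfile

_CATEGORY_COLORS = {"up": "crimson", "down": "royalblue", "unchanged": "0.6", "below_floor": "0.85"}


def scatter_differential(diff: DifferentialResult, path: str | Path, pseudo: float = 0.1) -> None:
    """Test-vs-reference RPM scatter with threshold-category colouring.

    Axes are log-scaled with a small display pseudocount so zero-RPM
    genes stay visible; dashed lines mark the fold threshold.
    """
    t = diff.table["test_rpm"] + pseudo
    r = diff.table["ref_rpm"] + pseudo
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for cat, color in _CATEGORY_COLORS.items():
        m = diff.table["category"] == cat
        ax.scatter(r[m], t[m], s=4, c=color, label=f"{cat} ({int(m.sum())})", alpha=0.6, lw=0)
    lims = [min(r.min(), t.min()), max(r.max(), t.max())]
    xs = np.geomspace(*lims)
    ax.plot(xs, xs, "k-", lw=0.5)
    ax.plot(xs, xs * diff.fold_threshold, "k--", lw=0.5)
    ax.plot(xs, xs / diff.fold_threshold, "k--", lw=0.5)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(f"{diff.ref_sample} (RPM)")
    ax.set_ylabel(f"{diff.test_sample} (RPM)")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_metagene(profiles: Sequence[MetageneProfile], path: str | Path) -> None:
    """Overlay metagene profiles from 0% (5') to 100% (3') of the transcript."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for p in profiles:
        ax.plot(np.arange(1, 101), p.values, label=f"{p.sample_id}/{p.set_id}")
    ax.set_xlabel("transcript position (% of mRNA length, 5'->3')")
    ax.set_ylabel(f"coverage ({profiles[0].mode} RPM/bin)")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
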