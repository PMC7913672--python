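"""Figure-style plots: composition, A/G rates, and the probability plot."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .caller import CandidateCall
from .rates import RateTable

__all__ = ["composition_plot", "rate_plot", "probability_plot"]

_BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


def composition_plot(rate_table: RateTable, path: str | Path) -> None:
    """Stacked per-position base composition (fraction of aligned reads)."""
    frac = rate_table.counts / rate_table.n_reads
    positions = np.arange(1, rate_table.length + 1)
    fig, ax = plt.subplots(figsize=(max(6, rate_table.length / 6), 3.2))
    bottom = np.zeros(rate_table.length)
    for i, base in enumerate("ACGT"):
        ax.bar(positions, 100 * frac[:, i], bottom=100 * bottom,
               color=_BASE_COLORS[base], width=0.85, label=base)
        bottom += frac[:, i]
    ax.set_xlabel("reference position")
    ax.set_ylabel("fraction of reads (%)")
    ax.set_ylim(0, 100)
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def rate_plot(rate_table: RateTable, path: str | Path) -> None:
    """Separated A-rate and G-rate bars at reference A positions."""
    a = rate_table.a_rate
    g = rate_table.g_rate
    fig, axes = plt.subplots(2, 1, figsize=(max(6, len(a) / 2), 4.5), sharex=True)
    axes[0].bar([str(p) for p in a.index], 100 * a.values, color=_BASE_COLORS["A"])
    axes[0].set_ylabel("A rate (%)")
    axes[0].set_ylim(0, 100)
    axes[1].bar([str(p) for p in g.index], 100 * g.values, color=_BASE_COLORS["G"])
    axes[1].set_ylabel("G rate (%)")
    axes[1].set_ylim(0, 100)
    axes[1].set_xlabel("reference A position")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def probability_plot(
    calls: Sequence[CandidateCall], path: str | Path, threshold: float = 0.95
) -> None:
    """Per-A-position probability statistic with the detection threshold line."""
    positions = [str(c.position) for c in calls]
    probs = [c.probability for c in calls]
    colors = ["#d62728" if c.is_candidate else "#7f7f7f" for c in calls]
    fig, ax = plt.subplots(figsize=(max(6, len(calls) / 2), 3.2))
    ax.bar(positions, probs, color=colors)
    ax.axhline(threshold, color="red", linewidth=1.2,
               label=f"detection threshold {threshold:g}")
    ax.set_xlabel("reference A position")
    ax.set_ylabel("probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
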