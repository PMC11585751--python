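"""Matplotlib figure writers for the concordance analyses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .concordance import BlandAltmanResult, ErrorHistogram

__all__ = ["plot_bland_altman", "plot_error_histogram"]


def plot_bland_altman(
    result: BlandAltmanResult, path: str | Path, title: str = ""
) -> None:
    """Difference-vs-mean scatter with dashed mean and limits of agreement."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=12, alpha=0.6)
    ax.axhline(result.mean_diff, color="tab:blue", linestyle="--",
               label=f"mean diff = {result.mean_diff:.2f}")
    for y, lab in ((result.loa_low, "LoA low"), (result.loa_high, "LoA high")):
        ax.axhline(y, color="tab:orange", linestyle="--", label=f"{lab} = {y:.2f}")
    ax.set_xlabel("mean of the two scores (%)")
    ax.set_ylabel("difference (pp)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_error_histogram(
    hist: ErrorHistogram, path: str | Path, title: str = ""
) -> None:
    """Bar chart of error counts per 10-point scoring bracket."""
    fig, ax = plt.subplots(figsize=(5, 4))
    centers = (hist.edges[:-1] + hist.edges[1:]) / 2.0
    ax.bar(centers, hist.counts, width=9)
    ax.set_xticks(hist.edges)
    ax.set_xlabel("absolute score error bracket (pp)")
    ax.set_ylabel("ROIs")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
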