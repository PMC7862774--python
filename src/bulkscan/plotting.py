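"""Per-chromosome Δ(SNP-index) figure."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_scan"]


def plot_scan(
    windows: pd.DataFrame,
    thresholds: pd.DataFrame | None = None,
    path: str | Path = "scan.png",
) -> None:
    """Window mean Δ(SNP-index) per chromosome, with the 99.9% threshold."""
    chroms = list(dict.fromkeys(windows["chrom"]))
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(3.2 * len(chroms), 2.6), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[0], chroms):
        sub = windows[(windows["chrom"] == chrom) & ~windows["flagged"]]
        mid = (sub["start"] + sub["end"]) / 2e6
        ax.plot(mid, sub["mean_delta"], lw=0.8, color="tab:blue")
        if thresholds is not None and "thr_0.999" in thresholds.columns:
            t = thresholds[thresholds["chrom"] == chrom]
            t = t.merge(sub[["start"]], on="start")
            ax.plot(
                (t["start"] + 250_000) / 1e6,
                t["thr_0.999"],
                lw=0.8,
                color="black",
                label="99.9% threshold",
            )
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_title(chrom, fontsize=9)
        ax.set_xlabel("Mb")
    axes[0][0].set_ylabel("Δ(SNP-index)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
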