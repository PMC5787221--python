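"""Δ(SNP-index) scan plot: per-site points, window mean, confidence bound."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_delta_scan(
    records: pd.DataFrame,
    window_stats: pd.DataFrame,
    regions=None,
    path: str | Path = "delta_scan.png",
) -> Path:
    """Write the classic QTL-seq figure for one chromosome.

    Grey dots: per-site Δ(SNP-index); black line: sliding-window mean
    (the smoothed statistic); red line: window-averaged 99% simulated
    null bound; shaded spans: called candidate regions.
    """
    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.plot(
        records["pos"] / 1e6, records["delta"],
        ".", color="0.75", ms=2, rasterized=True, label="site Δ(SNP-index)",
    )
    mid = (window_stats["start"] + window_stats["end"]) / 2 / 1e6
    ax.plot(mid, window_stats["mean_delta"], "k-", lw=1.2, label="window mean")
    if "mean_ci99" in window_stats.columns:
        ax.plot(mid, window_stats["mean_ci99"], "r-", lw=1.0, label="99% bound")
    for region in regions or []:
        ax.axvspan(region.start / 1e6, region.end / 1e6, color="orange", alpha=0.25)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("Δ(SNP-index)")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", fontsize=8, frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
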