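"""Disparity-curve and cohort figures.

Every plotting function returns the arrays it drew, so tests can assert on
the plotted data rather than rendered pixels.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cohort import PhylumSummary
from .io_formats import ResultRecord
from .replichore import ReplichoreModel
from .zcurve import DisparityCurves

__all__ = ["plot_disparity", "plot_zcc_boxplot", "plot_sign_percentages"]


def plot_disparity(
    curves: DisparityCurves,
    model: ReplichoreModel | None = None,
    path: str | Path | None = None,
) -> dict:
    """Plot AT and GC disparity tracks against position, with ori/ter markers."""
    n = np.arange(curves.length + 1)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(n, curves.at, label="AT disparity (A−T)", color="tab:blue")
    ax.plot(n, curves.gc, label="GC disparity (G−C)", color="tab:red")
    if model is not None:
        ax.axvline(model.ori, color="k", linestyle="--", linewidth=0.8, label="ori")
        ax.axvline(model.ter, color="gray", linestyle=":", linewidth=0.8, label="ter")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("cumulative base excess")
    ax.set_title(curves.genome_id)
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return {"n": n, "at": np.asarray(curves.at), "gc": np.asarray(curves.gc)}


def plot_zcc_boxplot(records: list[ResultRecord], path: str | Path | None = None) -> dict:
    """Boxplot of ZCC by phylum with Tukey whiskers (1.5 IQR) and outlier points."""
    groups: dict[str, list[float]] = {}
    for r in records:
        if r.zcc is None or r.zcc_degenerate:
            continue
        groups.setdefault(r.phylum or "(all)", []).append(r.zcc)
    if not groups:
        raise ValueError("no plottable ZCC values")
    phyla = sorted(groups)
    data = [groups[p] for p in phyla]
    fig, ax = plt.subplots(figsize=(max(4, len(phyla)), 4))
    bp = ax.boxplot(data, tick_labels=phyla, whis=1.5)
    outliers = {
        p: sorted(float(v) for v in fl.get_ydata()) for p, fl in zip(phyla, bp["fliers"])
    }
    ax.set_ylabel("ZCC index")
    ax.axhline(0.0, color="gray", linewidth=0.6)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return {"phyla": phyla, "values": data, "outliers": outliers}


def plot_sign_percentages(
    summaries: list[PhylumSummary], path: str | Path | None = None
) -> dict:
    """Stacked bar chart of positive/negative ZCC percentages per phylum."""
    if not summaries:
        raise ValueError("no phylum summaries to plot")
    phyla = [s.phylum for s in summaries]
    pos = [s.pct_positive for s in summaries]
    neg = [s.pct_negative for s in summaries]
    x = np.arange(len(phyla))
    fig, ax = plt.subplots(figsize=(max(4, len(phyla)), 4))
    ax.bar(x, neg, label="negative ZCC", color="tab:blue")
    ax.bar(x, pos, bottom=neg, label="positive ZCC", color="tab:orange")
    ax.set_xticks(x, phyla, rotation=45, ha="right")
    ax.set_ylabel("% of genomes")
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return {"phyla": phyla, "pct_positive": pos, "pct_negative": neg}
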