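"""Diagnostic plots for fitted screening results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import ScreeningReport


def plot_ahi_scatter(report: ScreeningReport, ax=None):
    """Estimated vs reference AHI with the identity line and the screening
    threshold; annotates the Pearson r."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    t = report.table
    ax.scatter(t["reference_ahi"], t["estimated_ahi"], s=18, alpha=0.8)
    lim = max(t["reference_ahi"].max(), t["estimated_ahi"].max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.axhline(report.threshold, color="grey", lw=0.8)
    ax.axvline(report.threshold, color="grey", lw=0.8)
    ax.set_xlabel("reference AHI (events/h)")
    ax.set_ylabel("estimated AHI (events/h)")
    ax.set_title(f"r = {report.pearson_r:.2f}")
    return ax


def plot_confusion(report: ScreeningReport, ax=None):
    """2x2 screening confusion matrix (rows: truth, cols: decision)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    cm = report.confusion
    ax.imshow(cm, cmap="Blues")
    for (i, j), v in np.ndenumerate(cm):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks([0, 1], [f"AHI<{report.threshold:g}", f"AHI>={report.threshold:g}"])
    ax.set_yticks([0, 1], [f"AHI<{report.threshold:g}", f"AHI>={report.threshold:g}"])
    ax.set_xlabel("decision")
    ax.set_ylabel("reference")
    return ax
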