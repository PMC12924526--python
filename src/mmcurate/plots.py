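"""Optional figures: F1-vs-IRR trendlines and patient timelines."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .drivers import trendlines


def plot_trendlines(design: pd.DataFrame, path: str | Path) -> None:
    """Scatter of per-field F1 against IRR-F1 with per-workflow OLS lines."""
    fits = trendlines(design)["fits"]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    xs = np.linspace(design["irr_f1"].min(), design["irr_f1"].max(), 50)
    for wf, grp in design.groupby("workflow_id"):
        pts = ax.scatter(grp["irr_f1"], grp["f1"], s=18, alpha=0.7, label=wf)
        row = fits[fits.workflow_id == wf].iloc[0]
        ax.plot(xs, row.intercept + row.slope * xs,
                color=pts.get_facecolor()[0], lw=1.5)
    ax.set_xlabel("IRR-F1 (abstraction difficulty)")
    ax.set_ylabel("workflow F1")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_timelines(timeline: pd.DataFrame, hist: pd.DataFrame,
                   path: str | Path, n_patients: int = 20) -> None:
    """Swimlanes for a few patients plus first-occurrence histograms."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 7),
                                   gridspec_kw={"height_ratios": [3, 2]})
    patients = sorted(timeline["patient_id"].unique())[:n_patients]
    labels = sorted(timeline["label"].unique())
    cmap = plt.get_cmap("tab10")
    color = {lbl: cmap(i % 10) for i, lbl in enumerate(labels)}
    for y, pid in enumerate(patients):
        sub = timeline[timeline.patient_id == pid]
        for r in sub.itertuples(index=False):
            ax1.scatter(r.offset_days, y, s=14,
                        color=color[r.label] if r.is_first else "0.7",
                        zorder=3 if r.is_first else 2)
    ax1.axvline(0, ls="--", color="k", lw=0.8)
    ax1.set_xlabel("days from index date")
    ax1.set_ylabel("patient")
    ax1.set_title("first occurrences colored; duplicates grey", fontsize=9)
    for lbl, grp in hist.groupby("label"):
        ax2.bar(grp["bin_left"], grp["count"], width=12, alpha=0.5,
                color=color.get(lbl, "0.5"), label=lbl)
    ax2.axvline(0, ls="--", color="k", lw=0.8)
    ax2.set_xlabel("first-occurrence offset (days)")
    ax2.set_ylabel("patients")
    ax2.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
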