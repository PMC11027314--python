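"""Diagnostic plots: the NMB-NAB scatter, bias-by-allele-length, ROC/PR."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

CATEGORY_COLORS = {
    "balanced": "tab:green",
    "loss": "tab:orange",
    "flux": "tab:blue",
    "local": "tab:purple",
    "outlier": "gray",
}


def nmb_nab_scatter(frame: pd.DataFrame, path, title: str = "") -> bool:
    """Scatter of sites in the NMB-NAB plane, colored by category.

    Unclassifiable sites are omitted. Returns False (no-op) on an empty
    report."""
    df = frame.dropna(subset=["NMB", "NAB"])
    if df.empty:
        return False
    fig, ax = plt.subplots(figsize=(5, 5))
    for cat, color in CATEGORY_COLORS.items():
        sub = df[df["category"] == cat]
        if len(sub):
            ax.scatter(sub["NMB"], sub["NAB"], s=8, c=color, label=cat, alpha=0.6)
    ax.axhline(0, lw=0.5, c="k")
    ax.axvline(0, lw=0.5, c="k")
    ax.set_xlabel("NMB (MB - SB)")
    ax.set_ylabel("NAB (AB - SB)")
    ax.set_xlim(-1, 1)
    ax.set_ylim(-1, 1)
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return True


def bias_by_length_plot(summary: pd.DataFrame, path, title: str = "") -> bool:
    """Medians with Q1/Q3 whiskers of the ALT fraction per length stratum."""
    if summary.empty:
        return False
    fig, ax = plt.subplots(figsize=(7, 4))
    for measure, grp in summary.groupby("measure"):
        grp = grp.sort_values("stratum")
        yerr = [grp["median"] - grp["q1"], grp["q3"] - grp["median"]]
        ax.errorbar(
            grp["stratum"], grp["median"], yerr=yerr, marker="o", ms=3,
            capsize=2, label=measure, lw=1,
        )
    ax.axhline(0.5, lw=0.5, c="k", ls="--")
    ax.set_xlabel("variant length (bp; <0 deletion, >0 insertion, 0 SNV)")
    ax.set_ylabel("ALT fraction")
    ax.legend()
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return True


def roc_pr_plot(evaluations: dict[str, dict], path, title: str = "") -> bool:
    """ROC and PR panels for one or more named score variants."""
    if not evaluations:
        return False
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    for name, ev in evaluations.items():
        ax1.plot(ev["fpr"], ev["tpr"], label=f"{name} (auc={ev['auc']:.3f})")
        ax2.plot(ev["recall"], ev["precision"], label=f"{name} (auprc={ev['auprc']:.3f})")
    ax1.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax1.set_xlabel("FPR")
    ax1.set_ylabel("TPR")
    ax1.legend(fontsize=8)
    ax2.set_xlabel("recall")
    ax2.set_ylabel("precision")
    ax2.legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return True
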