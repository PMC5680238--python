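"""Basic figures: rank/cumulative curve, M-A and volcano plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_rank_cumulative(ranked: pd.DataFrame, path: str | Path, top_n: int = 50) -> None:
    """Per-miRNA % contribution (dots) with cumulative % (squares)."""
    sub = ranked.head(top_n)
    fig, ax1 = plt.subplots(figsize=(8, 4))
    ax1.plot(sub["rank"], sub["pct"], "o", color="tab:blue", ms=4, label="% of pool")
    ax1.set_xlabel("abundance rank")
    ax1.set_ylabel("% of miRNA pool", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.plot(sub["rank"], sub["cumulative_pct"], "s", color="tab:brown", ms=4)
    ax2.set_ylabel("cumulative %", color="tab:brown")
    ax2.set_ylim(0, 105)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ma(records: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    sel = records.get("selected")
    colors = np.where(records["q"] <= 0.05, "tab:red", "0.6")
    ax.scatter(records["A"], records["M"], s=6, c=colors, alpha=0.7, lw=0)
    ax.axhline(0, color="k", lw=0.5)
    ax.axhline(1, color="k", lw=0.5, ls="--")
    ax.axhline(-1, color="k", lw=0.5, ls="--")
    ax.set_xlabel("A (mean log2 abundance)")
    ax.set_ylabel("M (log2 fold change)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_volcano(records: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    q = records["q"].clip(lower=1e-300)
    ax.scatter(records["M"], -np.log10(q), s=6, alpha=0.7, lw=0)
    ax.axhline(-np.log10(0.05), color="k", lw=0.5, ls="--")
    ax.set_xlabel("M (log2 fold change)")
    ax.set_ylabel("-log10 q")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
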