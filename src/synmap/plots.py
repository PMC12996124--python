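"""Figure outputs: MFI boxplots, mean +/- SEM radial profiles, PCC dot plots.

Plots are convenience artifacts; every plotted quantity also exists as a CSV
in the output tree, which is the authoritative record.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import AnalysisConfig


def mfi_boxplots(cell_df: pd.DataFrame, channels: Sequence[str], path: Path) -> None:
    """Per-cell MFI distribution per channel, grouped by condition."""
    inc = cell_df[cell_df["included"]]
    if inc.empty or not channels:
        return
    conditions = sorted(inc["condition"].unique())
    fig, axes = plt.subplots(1, len(channels), figsize=(3.2 * len(channels), 3.5), squeeze=False)
    for ax, ch in zip(axes[0], channels):
        data = [inc.loc[inc["condition"] == c, f"mfi_{ch}"].dropna() for c in conditions]
        ax.boxplot(data, tick_labels=conditions)
        ax.set_title(ch)
        ax.set_ylabel("MFI")
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def profile_plots(out: Path, conditions: Sequence[str], channels: Sequence[str]) -> None:
    """Mean +/- SEM radial intensity profiles, one figure per condition."""
    for cond in conditions:
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        plotted = False
        for ch in channels:
            table = out / str(cond) / f"profile_{ch}.csv"
            if not table.exists():
                continue
            df = pd.read_csv(table)
            ax.plot(df["bin"], df["mean"], label=ch)
            ax.fill_between(
                df["bin"], df["mean"] - df["sem"].fillna(0), df["mean"] + df["sem"].fillna(0), alpha=0.25
            )
            plotted = True
        if plotted:
            ax.set_xlabel("radius bin")
            ax.set_ylabel("MFI (normalized)")
            ax.set_title(str(cond))
            ax.legend(fontsize=8)
            fig.tight_layout()
            fig.savefig(out / "plots" / f"profiles_{cond}.png", dpi=120)
        plt.close(fig)


def pcc_plots(cell_df: pd.DataFrame, path: Path) -> None:
    """Per-cell PCC dots with per-replicate medians, per channel pair."""
    inc = cell_df[cell_df["included"]]
    pcc_cols = [c for c in inc.columns if c.startswith("pcc_")]
    if inc.empty or not pcc_cols:
        return
    conditions = sorted(inc["condition"].unique())
    fig, axes = plt.subplots(1, len(pcc_cols), figsize=(2.6 * len(pcc_cols), 3.5), squeeze=False)
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for ax, col in zip(axes[0], pcc_cols):
        for i, cond in enumerate(conditions):
            grp = inc[inc["condition"] == cond]
            vals = grp[col].dropna()
            ax.plot(i + rng.uniform(-0.15, 0.15, vals.size), vals, ".", color="gray", ms=3, alpha=0.6)
            med = vals.median()
            if np.isfinite(med):
                ax.plot([i - 0.25, i + 0.25], [med, med], "-", color="black", lw=1.5)
            for _, rep_grp in grp.groupby("replicate"):
                rv = rep_grp[col].dropna().median()
                if np.isfinite(rv):
                    ax.plot(i, rv, "D", color="purple", ms=5)
        ax.set_xticks(range(len(conditions)))
        ax.set_xticklabels(conditions, rotation=45)
        ax.set_ylim(-1.05, 1.05)
        ax.set_title(col[len("pcc_"):].replace("__", " vs "), fontsize=9)
        ax.set_ylabel("PCC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_all(out: Path, cell_df: pd.DataFrame, channels: Sequence[str], config: AnalysisConfig) -> None:
    plots_dir = out / "plots"
    plots_dir.mkdir(parents=True, exist_ok=True)
    mfi_boxplots(cell_df, channels, plots_dir / "mfi_boxplots.png")
    if not cell_df.empty:
        profile_plots(out, sorted(cell_df["condition"].unique()), channels)
    pcc_plots(cell_df, plots_dir / "pcc.png")
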