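"""Minimal diagnostic plots (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats


def dominance_bars(summary, path: str | Path) -> None:
    """Stacked horizontal bars of per-tissue dominance percentages."""
    tissues = summary["tissue"].tolist()
    a = summary["A_dominant_pct"].to_numpy()
    bal = summary["balanced_pct"].to_numpy()
    b = summary["B_dominant_pct"].to_numpy()
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(tissues) + 1.5))
    y = np.arange(len(tissues))
    ax.barh(y, a, color="#d95f02", label="A-dominant")
    ax.barh(y, bal, left=a, color="#cccccc", label="balanced")
    ax.barh(y, b, left=a + bal, color="#1b9e77", label="B-dominant")
    ax.set_yticks(y, tissues)
    ax.set_xlabel("% of assessable homoeolog pairs")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ratio_tracks(windows, chromosome: str, path: str | Path,
                 del_threshold: float = 0.35, dup_threshold: float = 1.65) -> None:
    """Smoothed coverage-ratio line plot for one chromosome, all accessions."""
    fig, ax = plt.subplots(figsize=(9, 3.5))
    for wt in windows:
        if wt.chromosome != chromosome or len(wt) == 0:
            continue
        ax.plot(wt.start_bp / 1e3, wt.mean_ratio, lw=0.6, alpha=0.5)
    ax.axhline(del_threshold, color="red", ls="--", lw=0.8)
    ax.axhline(dup_threshold, color="blue", ls="--", lw=0.8)
    ax.set_xlabel(f"{chromosome} position (kb)")
    ax.set_ylabel("coverage ratio (window mean)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ks_histogram(lnks, fit, path: str | Path) -> None:
    """ln(Ks) histogram with the fitted mixture density."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(lnks, bins=60, density=True, color="#bbbbbb")
    grid = np.linspace(min(lnks), max(lnks), 400)
    density = np.zeros_like(grid)
    for w, m, s in zip(fit.weights, fit.means, fit.sds):
        density += w * stats.norm.pdf(grid, m, s)
    ax.plot(grid, density, color="black", lw=1.5)
    ax.set_xlabel("ln(Ks)")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
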