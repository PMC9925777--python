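"""Diagnostic figures: persistence diagrams, patch score maps, group box plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .persistence import PersistenceDiagram
from .statistics import STAT_COLUMNS

__all__ = ["plot_diagram", "plot_scoremap", "plot_group_boxes", "significance_stars"]


def significance_stars(p: float) -> str:
    """Star annotation for an adjusted p-value ('ns' above 0.05)."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 5e-2:
        return "*"
    return "ns"


def plot_diagram(diag: PersistenceDiagram, path=None, ax=None):
    """Birth/death scatter per dimension with the diagonal; the essential
    point is drawn at a capped ordinate and labelled with the infinity sign."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    pts = [p for p in (diag.h0, diag.h1) if p.size]
    finite_vals = np.concatenate([p.ravel() for p in pts]) if pts else np.array([0.0])
    if not diag.degenerate and np.isfinite(diag.essential_birth):
        finite_vals = np.append(finite_vals, diag.essential_birth)
    lo = finite_vals.min() - 1
    hi = finite_vals.max() + 1
    cap = hi + 0.08 * (hi - lo)
    ax.plot([lo, cap], [lo, cap], color="grey", lw=0.8, zorder=0)
    ax.axhline(0, color="lightgrey", lw=0.6, zorder=0)
    ax.axvline(0, color="lightgrey", lw=0.6, zorder=0)
    if diag.h0.size:
        ax.scatter(diag.h0[:, 0], diag.h0[:, 1], s=14, c="tab:blue", label="$H_0$")
    if diag.h1.size:
        ax.scatter(diag.h1[:, 0], diag.h1[:, 1], s=20, c="tab:green", marker="D",
                   label="$H_1$")
    if not diag.degenerate and np.isfinite(diag.essential_birth):
        ax.scatter([diag.essential_birth], [cap], s=30, c="tab:blue", marker="^")
        ax.annotate(r"$\infty$", (diag.essential_birth, cap),
                    textcoords="offset points", xytext=(4, 2))
    ax.set_xlabel("birth")
    ax.set_ylabel("death")
    if diag.h0.size or diag.h1.size:
        ax.legend(loc="lower right", frameon=False)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_scoremap(score_map: np.ma.MaskedArray, path=None, ax=None, label: str = "score"):
    """Heat map of a per-patch statistic; no-data tiles drawn distinctly."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("lightgrey")
    im = ax.imshow(score_map, cmap=cmap)
    fig.colorbar(im, ax=ax, label=label)
    ax.set_xlabel("patch column")
    ax.set_ylabel("patch row")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_group_boxes(
    panel: pd.DataFrame,
    statistic: str,
    grouping: str = "genotype",
    path=None,
    ax=None,
    p_adjusted: float | None = None,
):
    """Per-group box plots of one statistic (median/quartiles, 1.5*IQR
    whiskers), optionally annotated with the significance stars of an
    adjusted p-value from the comparison suite."""
    if statistic not in panel.columns:
        valid = [c for c in panel.columns if c in STAT_COLUMNS]
        raise ValueError(f"unknown statistic {statistic!r}; valid names: {valid}")
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    groups = list(pd.unique(panel[grouping]))
    data = [panel.loc[panel[grouping] == g, statistic].dropna().to_numpy() for g in groups]
    ax.boxplot(data, tick_labels=[str(g) for g in groups], whis=1.5)
    ax.set_ylabel(statistic)
    ax.set_xlabel(grouping)
    if p_adjusted is not None and len(groups) == 2:
        top = max((d.max() for d in data if d.size), default=0)
        ax.plot([1, 2], [top * 1.05 + 0.5] * 2, color="black", lw=1)
        ax.text(1.5, top * 1.05 + 0.5, significance_stars(p_adjusted),
                ha="center", va="bottom")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
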