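"""Figures: tracking quality, confusion matrices, and lasagna plots."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .activity import LEVELS
from .evaluation import GroundTruthTrace
from .filtering import LocalizationTrace

LASAGNA_ORDERINGS = ("absolute", "relative", "route")


def plot_tracking(
    trace: LocalizationTrace | Sequence[str],
    truth: GroundTruthTrace,
    out_path,
    epoch_s: float = 10.0,
):
    """Step plot of criterion (red) vs estimated (blue) area index over time."""
    fig, ax = plt.subplots(figsize=(10, 4))
    if isinstance(trace, LocalizationTrace):
        pred = trace.smoothed_area_ids()
        order = trace.area_ids
    else:
        pred = list(trace)
        order = sorted(set(truth.area_ids) | set(pred))
    idx = {a: i for i, a in enumerate(order)}
    if truth.n_epochs:
        t = np.arange(truth.n_epochs) * epoch_s
        ax.step(t, [idx[a] for a in truth.area_ids], where="post",
                color="red", label="criterion")
    if pred:
        t = np.arange(len(pred)) * epoch_s
        ax.step(t, [idx[a] for a in pred], where="post",
                color="blue", alpha=0.7, label="algorithm")
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order, fontsize=7)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("area")
    if ax.get_legend_handles_labels()[0]:
        ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_confusion(cm: pd.DataFrame, out_path, title: str = ""):
    """Heatmap of a row-normalized area confusion matrix."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.to_numpy(), vmin=0.0, vmax=1.0, cmap="Blues")
    ax.set_xticks(range(len(cm.columns)))
    ax.set_xticklabels(cm.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(cm.index)))
    ax.set_yticklabels(cm.index, fontsize=7)
    ax.set_xlabel("predicted area")
    ax.set_ylabel("true area")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="fraction of true-area time")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def lasagna_table(
    areas_per_epoch: Sequence[str],
    levels_per_epoch: Sequence[str],
    ordering: str = "absolute",
    epoch_s: float = 10.0,
) -> pd.DataFrame:
    """Area × activity-level table of accumulated seconds, rows ordered.

    Orderings: ``absolute`` — descending total time per area; ``relative`` —
    descending fraction of the area's time at low activity; ``route`` —
    first-visit order along the trace.
    """
    if ordering not in LASAGNA_ORDERINGS:
        raise ValueError(f"unknown ordering {ordering!r}; expected {LASAGNA_ORDERINGS}")
    if len(areas_per_epoch) != len(levels_per_epoch):
        raise ValueError("trace and activity levels must be epoch-aligned")
    df = pd.DataFrame({"area": areas_per_epoch, "level": levels_per_epoch})
    table = (
        df.groupby(["area", "level"]).size().unstack(fill_value=0) * epoch_s
    )
    for lv in LEVELS:
        if lv not in table.columns:
            table[lv] = 0.0
    table = table[list(LEVELS)].astype(float)
    if ordering == "absolute":
        order = table.sum(axis=1).sort_values(ascending=False, kind="stable").index
    elif ordering == "relative":
        frac_low = table["low"] / table.sum(axis=1).replace(0.0, np.nan)
        order = frac_low.sort_values(ascending=False, kind="stable").index
    else:  # route: first appearance along the trace
        seen: list[str] = []
        for a in areas_per_epoch:
            if a not in seen:
                seen.append(a)
        order = [a for a in seen if a in table.index]
    return table.loc[order]


def plot_lasagna(
    trace: LocalizationTrace | Sequence[str],
    levels_per_epoch: Sequence[str],
    out_path,
    ordering: str = "absolute",
    epoch_s: float = 10.0,
):
    """Heatmap of time per (area, activity level), rows ordered as requested."""
    areas = (
        trace.smoothed_area_ids() if isinstance(trace, LocalizationTrace) else list(trace)
    )
    table = lasagna_table(areas, levels_per_epoch, ordering=ordering, epoch_s=epoch_s)
    fig, ax = plt.subplots(figsize=(5, 0.4 * max(len(table), 4) + 1.5))
    im = ax.imshow(table.to_numpy(), aspect="auto", cmap="viridis", vmin=0.0)
    ax.set_xticks(range(len(table.columns)))
    ax.set_xticklabels(table.columns)
    ax.set_yticks(range(len(table.index)))
    ax.set_yticklabels(table.index, fontsize=8)
    ax.set_xlabel("activity level")
    fig.colorbar(im, ax=ax, label="time (s)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
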