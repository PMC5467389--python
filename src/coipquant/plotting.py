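"""Matplotlib helpers hanging off the Results objects."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_xic_trace(trace, ax=None):
    """Intensity vs retention time for one extracted trace."""
    ax = _get_ax(ax)
    ax.plot(trace.rt_grid, trace.intensities, marker=".", lw=1)
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("intensity")
    if trace.label:
        ax.set_title(trace.label)
    return ax


def plot_delta_ratios(deltas: pd.DataFrame, fraction: str = "S3", ax=None):
    """Log2 lesion/intact ratio per protein for one fraction, colored by class."""
    ax = _get_ax(ax)
    sel = deltas[(deltas["fraction"] == fraction) & deltas["ratio_defined"]]
    colors = {
        "increased": "tab:red",
        "decreased": "tab:blue",
        "unchanged": "gray",
        "filtered_out": "lightgray",
    }
    y = np.log2(sel["ratio"].to_numpy(dtype=float))
    ax.scatter(
        sel["fraction_total"],
        y,
        c=[colors.get(c, "k") for c in sel["classification"]],
        s=18,
    )
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xscale("log")
    ax.set_xlabel("fraction total spectral counts")
    ax.set_ylabel("log2 lesion/intact")
    ax.set_title(f"{fraction} fraction")
    return ax


def plot_occupancy(occupancies: pd.DataFrame, target: str, ax=None):
    """Per-sample occupancy of one phosphosite, intact vs lesion."""
    ax = _get_ax(ax)
    sel = occupancies[occupancies["target"] == target]
    for i, hemi in enumerate(("intact", "lesion")):
        vals = sel[sel["hemisphere"] == hemi]["occupancy"].to_numpy(dtype=float)
        ax.scatter(np.full(vals.size, i), vals, alpha=0.7)
        if vals.size:
            ax.hlines(vals.mean(), i - 0.2, i + 0.2, color="k")
    ax.set_xticks([0, 1], ["intact", "lesion"])
    ax.set_ylabel("phospho-occupancy")
    ax.set_title(target)
    return ax


def plot_blot_cells(table: pd.DataFrame, factors, ax=None):
    """Mean +- SEM of the reference-normalized blot ratio per design cell."""
    ax = _get_ax(ax)
    grouped = table.groupby(list(factors))["ratio"]
    means, sems = grouped.mean(), grouped.sem()
    labels = ["\n".join(map(str, k)) for k in means.index]
    x = np.arange(len(means))
    ax.bar(x, means.to_numpy(), yerr=sems.to_numpy(), capsize=3, color="lightsteelblue")
    ax.set_xticks(x, labels)
    ax.set_ylabel("normalized co-IP ratio")
    return ax
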