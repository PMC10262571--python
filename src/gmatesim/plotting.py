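"""Generic plots: genetic trends, inbreeding trends, effect profiles, frontiers."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .mating import Frontier

__all__ = ["plot_trend", "plot_effect_profile", "plot_frontier"]


def plot_trend(metrics: pd.DataFrame, value: str = "mean_gebv", ax=None):
    """Per-generation trend of a metric, one line per scheme (replicate mean)."""
    if ax is None:
        _, ax = plt.subplots()
    for scheme, grp in metrics.groupby("scheme", sort=False):
        trend = grp.groupby("generation")[value].mean()
        ax.plot(trend.index, trend.to_numpy(), marker="o", label=scheme)
    ax.set_xlabel("generation")
    ax.set_ylabel(value)
    ax.legend(fontsize="small")
    return ax


def plot_effect_profile(effects_df: pd.DataFrame, ax=None):
    """Estimated marker effects along the genome (chromosomes concatenated)."""
    if ax is None:
        _, ax = plt.subplots()
    offset = 0.0
    for _, grp in effects_df.groupby("chromosome"):
        x = grp["pos_cM"].to_numpy() + offset
        ax.vlines(x, 0, grp["effect"].to_numpy(), lw=0.5)
        offset = x.max()
    ax.set_xlabel("genome position (cM, concatenated)")
    ax.set_ylabel("estimated marker effect")
    return ax


def plot_frontier(frontier: Frontier, ax=None):
    """Gain vs. inbreeding of the nondominated plans, with endpoints marked."""
    if ax is None:
        _, ax = plt.subplots()
    gains = np.array([e.gain for e in frontier.entries])
    inbs = np.array([e.inbreeding for e in frontier.entries])
    order = np.argsort(inbs)
    ax.plot(inbs[order], gains[order], "o-", ms=4)
    mg, mi = frontier.max_gain, frontier.min_inbreeding
    ax.plot(mg.inbreeding, mg.gain, "r^", ms=9, label="max gain")
    ax.plot(mi.inbreeding, mi.gain, "gv", ms=9, label="min inbreeding")
    ax.set_xlabel("Inbreeding(P)")
    ax.set_ylabel("Gain(P)")
    ax.legend()
    return ax
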