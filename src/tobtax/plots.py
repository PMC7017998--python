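"""Figures: trend lines with tax-event markers, forest plots, shift plots."""
from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .summaries import GrowthComparison, WeightedSeries

#: default tax-change months (first month priced under each new regime) and
#: the standardised-packaging implementation period, on the May-2015 index
DEFAULT_EVENT_MONTHS = (12, 24, 26, 32)
IMPLEMENTATION_PERIOD = (13, 25)   # May 2016 - May 2017


def trend_plot(series: Mapping[str, WeightedSeries], ylabel: str,
               event_months: Sequence[int] = DEFAULT_EVENT_MONTHS,
               shade: tuple[int, int] | None = IMPLEMENTATION_PERIOD):
    """Line plot of weighted series with CI bands and event markers."""
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for label, s in series.items():
        ax.plot(s.months, s.estimate, label=label)
        if s.lo is not None:
            ax.fill_between(s.months, s.lo, s.hi, alpha=0.2)
    for m in event_months:
        ax.axvline(m, color="grey", linestyle="--", linewidth=0.8)
    if shade is not None:
        ax.axvspan(shade[0], shade[1], color="grey", alpha=0.12)
    ax.set_xlabel("month index (1 = May 2015)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def forest_plot(comparisons: Sequence[GrowthComparison], title: str = ""):
    """Pre/post mean monthly growth per stratum, pence per stick per month."""
    fig, ax = plt.subplots(figsize=(7, 0.6 * max(len(comparisons), 4) + 1))
    y = 0
    ticks, labels = [], []
    for c in comparisons:
        for est, off, color, tag in ((c.pre, 0.15, "tab:blue", "pre"),
                                     (c.post, -0.15, "tab:red", "post")):
            ax.errorbar([est.estimate * 100], [y + off],
                        xerr=[[(est.estimate - est.lo) * 100],
                              [(est.hi - est.estimate) * 100]],
                        fmt="o", color=color, markersize=4,
                        label=tag if y == 0 else None)
        ticks.append(y)
        labels.append(c.label)
        y -= 1
    ax.axvline(0, color="grey", linewidth=0.8)
    ax.set_yticks(ticks)
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("mean monthly change (pence/stick)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def shift_plot(shift_table: pd.DataFrame, title: str = ""):
    """Post-event net revenue change by horizon and stratum."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, grp in shift_table.groupby("label"):
        ax.errorbar(grp["horizon"], grp["delta_pence"],
                    yerr=[grp["delta_pence"] - grp["lo"],
                          grp["hi"] - grp["delta_pence"]],
                    marker="o", capsize=2, label=label)
    ax.axhline(0, color="grey", linewidth=0.8)
    ax.set_xlabel("months after budget month")
    ax.set_ylabel("change in weighted net revenue (pence/stick)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
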