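"""Volume-weighted series, price gaps, window growth and tax shifting.

All interval estimates come from posterior simulation of the fitted model
coefficients: draws from N(params, Vp) are pushed through the (linear)
weighted-average operator, so any derived quantity -- a weighted average
price (WAP), a gap between two strata, a growth rate, a post-event net
revenue change -- keeps the full cross-month and cross-stratum coefficient
correlation, and its 95% interval is read off the draw percentiles.

Market shares are the observed monthly volumes within the stratum (shares
are time-varying); ``fixed_weights=True`` freezes each SKU's share at its
study-period average volume as a sensitivity variant.

Tax shifting after a budget event is classified from the change in weighted
net revenue h months after the budget month: an interval entirely below
zero is undershifting (the industry absorbed part of the rise), entirely
above zero overshifting, anything else indeterminate.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import TrendResults

logger = logging.getLogger(__name__)

STRATA = ("overall", "product_type", "segment")

# default forest-plot windows (month indices, closed): the same ten calendar
# months (June..March) before and after full implementation
PRE_WINDOW = (2, 11)        # Jun 2015 - Mar 2016
POST_WINDOW = (26, 35)      # Jun 2017 - Mar 2018
ALT_RYO_POST_WINDOW = (14, 23)  # Jun 2016 - Mar 2017


def simulate_coefficients(results: TrendResults, n_draws: int = 10000,
                          seed=None) -> np.ndarray:
    """(n_draws, p) coefficient draws from the fitted model."""
    return results.simulate_params(n_draws, seed=seed)


@dataclass
class WeightedSeries:
    """Per-month volume-weighted mean of a modelled quantity, with draws."""

    stratum: str
    label: str
    months: np.ndarray
    estimate: np.ndarray
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    draws: np.ndarray | None = None   # (n_months, n_draws)

    def to_frame(self) -> pd.DataFrame:
        d = {"stratum": self.stratum, "label": self.label,
             "month": self.months, "estimate": self.estimate}
        if self.lo is not None:
            d["lo"] = self.lo
            d["hi"] = self.hi
        return pd.DataFrame(d)

    def at(self, month: int) -> float:
        i = int(np.flatnonzero(self.months == month)[0])
        return float(self.estimate[i])

    def _index(self, month: int) -> int:
        w = np.flatnonzero(self.months == month)
        if not len(w):
            raise ValueError(f"month {month} not in series")
        return int(w[0])


def _stratum_labels(records: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "overall":
        return pd.Series("all", index=records.index)
    if stratum in ("product_type", "segment"):
        return records[stratum]
    raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")


def _weights(records: pd.DataFrame, labels: pd.Series,
             fixed_weights: bool) -> np.ndarray:
    vol = records["volume_sticks"].to_numpy(dtype=float)
    if fixed_weights:
        mean_vol = records.groupby("sku_id")["volume_sticks"].transform("mean")
        vol = mean_vol.to_numpy(dtype=float)
    return vol


def weighted_average_series(results: TrendResults, records: pd.DataFrame,
                            draws: np.ndarray,
                            stratum: str = "overall",
                            ci: float = 0.95,
                            fixed_weights: bool = False
                            ) -> dict[str, WeightedSeries]:
    """WAP (or weighted net revenue) series per stratum label.

    For each draw and month, the modelled per-record value is averaged with
    market-share weights; the point estimate is the mean over draws and the
    interval the central ``ci`` draw percentiles.
    """
    X = results.design.matrix(records)
    labels = _stratum_labels(records, stratum)
    vol = _weights(records, labels, fixed_weights)
    months = records["month"].to_numpy()
    out: dict[str, WeightedSeries] = {}
    alpha = (1.0 - ci) / 2.0
    for label in sorted(labels.unique()):
        sel_l = (labels == label).to_numpy()
        ms = np.unique(months[sel_l])
        rows_M = []
        keep_months = []
        for m in ms:
            sel = sel_l & (months == m)
            tot = vol[sel].sum()
            if tot <= 0:
                logger.warning("stratum %r month %d has zero volume; omitted",
                               label, m)
                continue
            w = vol[sel] / tot
            rows_M.append(w @ X[sel])
            keep_months.append(m)
        if not rows_M:
            continue
        M = np.vstack(rows_M)
        series_draws = M @ draws.T  # (n_months, n_draws)
        est = series_draws.mean(axis=1)
        lo = np.quantile(series_draws, alpha, axis=1)
        hi = np.quantile(series_draws, 1.0 - alpha, axis=1)
        out[label] = WeightedSeries(stratum=stratum, label=str(label),
                                    months=np.asarray(keep_months),
                                    estimate=est, lo=lo, hi=hi,
                                    draws=series_draws)
    return out


def observed_weighted_series(records: pd.DataFrame, value_col: str,
                             stratum: str = "overall",
                             fixed_weights: bool = False
                             ) -> dict[str, WeightedSeries]:
    """Volume-weighted series of an observed column (no model, no CI)."""
    labels = _stratum_labels(records, stratum)
    vol = _weights(records, labels, fixed_weights)
    months = records["month"].to_numpy()
    vals = records[value_col].to_numpy(dtype=float)
    out = {}
    for label in sorted(labels.unique()):
        sel_l = (labels == label).to_numpy()
        ms = []
        est = []
        for m in np.unique(months[sel_l]):
            sel = sel_l & (months == m)
            tot = vol[sel].sum()
            if tot <= 0:
                continue
            ms.append(m)
            est.append(float(vals[sel] @ (vol[sel] / tot)))
        out[label] = WeightedSeries(stratum=stratum, label=str(label),
                                    months=np.asarray(ms),
                                    estimate=np.asarray(est))
    return out


def gap_series(expensive: WeightedSeries, cheap: WeightedSeries,
               ci: float = 0.95) -> WeightedSeries:
    """Per-draw difference WAP(expensive) - WAP(cheap) on common months."""
    if expensive.draws is None or cheap.draws is None:
        raise ValueError("gap_series needs draw-bearing series")
    common, ia, ib = np.intersect1d(expensive.months, cheap.months,
                                    return_indices=True)
    if not len(common):
        raise ValueError("series share no months")
    d = expensive.draws[ia] - cheap.draws[ib]
    alpha = (1.0 - ci) / 2.0
    return WeightedSeries(
        stratum="gap", label=f"{expensive.label} - {cheap.label}",
        months=common, estimate=d.mean(axis=1),
        lo=np.quantile(d, alpha, axis=1),
        hi=np.quantile(d, 1.0 - alpha, axis=1), draws=d)


@dataclass
class GrowthEstimate:
    """Mean monthly change (GBP/stick/month) over a closed month window."""

    window: tuple[int, int]
    estimate: float
    lo: float
    hi: float
    draws: np.ndarray | None = None


def window_growth(series: WeightedSeries, window: tuple[int, int],
                  ci: float = 0.95) -> GrowthEstimate:
    """Average monthly change over the window, with a simulation interval.

    The mean of successive month differences over a contiguous window equals
    the endpoint difference divided by the window length minus one.
    """
    a, b = window
    if b - a < 1:
        raise ValueError("window must span at least 2 months")
    ia, ib = series._index(a), series._index(b)
    missing = set(range(a, b + 1)) - set(series.months.tolist())
    if missing:
        raise ValueError(f"window months missing from series: {sorted(missing)}")
    if series.draws is None:
        g = (series.estimate[ib] - series.estimate[ia]) / (b - a)
        return GrowthEstimate(window, float(g), float(g), float(g))
    d = (series.draws[ib] - series.draws[ia]) / (b - a)
    alpha = (1.0 - ci) / 2.0
    return GrowthEstimate(window, float(d.mean()),
                          float(np.quantile(d, alpha)),
                          float(np.quantile(d, 1.0 - alpha)), draws=d)


@dataclass
class GrowthComparison:
    """Pre- vs post-window growth with the per-draw difference interval."""

    label: str
    pre: GrowthEstimate
    post: GrowthEstimate
    diff_estimate: float = 0.0
    diff_lo: float = 0.0
    diff_hi: float = 0.0


def growth_comparison(series: WeightedSeries,
                      window_pre: tuple[int, int] = PRE_WINDOW,
                      window_post: tuple[int, int] = POST_WINDOW,
                      ci: float = 0.95) -> GrowthComparison:
    if (window_pre[1] - window_pre[0]) != (window_post[1] - window_post[0]):
        raise ValueError("pre and post windows must have equal length")
    pre = window_growth(series, window_pre, ci)
    post = window_growth(series, window_post, ci)
    if pre.draws is None or post.draws is None:
        raise ValueError("growth comparison needs draw-bearing series")
    d = post.draws - pre.draws
    alpha = (1.0 - ci) / 2.0
    return GrowthComparison(label=series.label, pre=pre, post=post,
                            diff_estimate=float(d.mean()),
                            diff_lo=float(np.quantile(d, alpha)),
                            diff_hi=float(np.quantile(d, 1.0 - alpha)))


def classify_shift(lo: float, hi: float) -> str:
    """CI sign rule: entirely below zero -> undershift, above -> overshift."""
    if hi < 0.0:
        return "undershift"
    if lo > 0.0:
        return "overshift"
    return "indeterminate"


def shift_analysis(series_by_label: Mapping[str, WeightedSeries],
                   event_month: int,
                   horizons: Sequence[int] = (1, 2, 3, 4, 5),
                   ci: float = 0.95) -> pd.DataFrame:
    """Post-event change in weighted net revenue, in pence per stick.

    For each stratum and horizon h, delta_h = NR(event_month + h) -
    NR(event_month) per coefficient draw; the event month is the budget
    month, still priced and taxed under the old regime.  Horizons running
    past the series end are truncated with a warning.
    """
    alpha = (1.0 - ci) / 2.0
    rows = []
    for label, s in series_by_label.items():
        if s.draws is None:
            raise ValueError("shift_analysis needs draw-bearing series")
        if event_month not in s.months:
            raise ValueError(f"event month {event_month} not in series {label!r}")
        i0 = s._index(event_month)
        for h in horizons:
            if event_month + h > s.months.max():
                warnings.warn(f"horizon {h} truncated for {label!r}: series "
                              f"ends at month {s.months.max()}")
                continue
            ih = s._index(event_month + h)
            d = (s.draws[ih] - s.draws[i0]) * 100.0  # GBP -> pence
            lo = float(np.quantile(d, alpha))
            hi = float(np.quantile(d, 1.0 - alpha))
            rows.append({"label": label, "event_month": event_month,
                         "horizon": h, "delta_pence": float(d.mean()),
                         "lo": lo, "hi": hi,
                         "classification": classify_shift(lo, hi)})
    return pd.DataFrame(rows)
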