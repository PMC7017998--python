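"""UK tobacco tax engine.

Decomposes a retail pack price into excise duty, VAT and industry net
revenue on a per-stick basis, under a timeline of duty regimes.

The UK taxes factory-made cigarettes (FM) with a specific duty (GBP per
1,000 sticks) plus an ad valorem duty (a fraction of retail price), and
roll-your-own tobacco (RYO) with a specific duty per kilogram only.  VAT
applies to both.  From May 2017 a Minimum Excise Tax (MET) put a floor
under total FM excise: duty is the *higher* of

    A. specific + ad_valorem * retail price (per 1,000 sticks), or
    B. a fixed floor amount per 1,000 sticks.

RYO quantities are converted to "stick equivalents" at a fixed weight per
stick (0.5 g by default), and the same constant is used for RYO duty so
per-stick figures are internally consistent.

Net revenue -- price minus all taxes -- is the industry/retail take and is
the profitability proxy used downstream.  Taxes are always computed on
nominal prices in the month of sale (duty is levied in nominal terms; in
particular the MET branch depends on the nominal price); prices and net
revenue are each deflated to base-month money afterwards.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .months import DEFAULT_MONTH0, to_index

logger = logging.getLogger(__name__)

#: RYO stick-equivalent weight, grams per stick.
GRAMS_PER_STICK = 0.5


class TaxError(ValueError):
    pass


@dataclass(frozen=True)
class TaxRegime:
    """One duty regime, effective from ``effective_month`` (inclusive).

    ``specific_fm_per_1000`` is GBP per 1,000 cigarettes,
    ``specific_ryo_per_kg`` GBP per kg of loose tobacco,
    ``advalorem_fm`` a fraction of FM retail price (FM only),
    ``vat_rate`` the statutory VAT rate (fraction of tax-exclusive price),
    ``met_per_1000`` the MET floor in GBP per 1,000 cigarettes, or None.
    """

    effective_month: int
    specific_fm_per_1000: float
    specific_ryo_per_kg: float
    advalorem_fm: float = 0.165
    vat_rate: float = 0.20
    met_per_1000: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        for field in ("specific_fm_per_1000", "specific_ryo_per_kg",
                      "advalorem_fm", "vat_rate"):
            if getattr(self, field) < 0:
                raise TaxError(f"{field} must be >= 0")
        if self.met_per_1000 is not None and self.met_per_1000 < 0:
            raise TaxError("met_per_1000 must be >= 0")


@dataclass(frozen=True)
class TaxBreakdown:
    """Per-stick decomposition: price = excise + VAT + net revenue exactly."""

    price_per_stick: float
    excise_per_stick: float
    vat_per_stick: float
    net_revenue_per_stick: float
    met_applied: bool

    @property
    def negative_net_revenue(self) -> bool:
        return self.net_revenue_per_stick < 0


# Statutory UK rates May 2015 - April 2018 (budget date, FM specific GBP per
# 1000, RYO specific GBP per kg, MET floor GBP per 1000 or None).  Ad valorem
# (16.5%) and VAT (20%) were unchanged throughout.
_UK_ROWS = [
    ("2015-05", 189.49, 185.74, None, "baseline May 2015"),
    ("2016-03", 196.42, 198.10, None, "budget 16 Mar 2016"),
    ("2017-03", 207.99, 209.77, None, "budget 8 Mar 2017"),
    ("2017-05", 207.99, 209.77, 268.63, "MET from 20 May 2017"),
    ("2017-11", 217.23, 221.18, 280.15, "budget 22 Nov 2017"),
]


def uk_timeline(snap: str = "next_month",
                month0: str = DEFAULT_MONTH0) -> list[TaxRegime]:
    """Statutory UK regime timeline for the May 2015 - April 2018 window.

    Budget changes fell mid-month (16 Mar 2016, 8 Mar 2017, 20 May 2017,
    22 Nov 2017); with monthly data a convention is needed.  The default
    ``snap="next_month"`` makes each change effective from the following
    full month (the budget month itself is still priced under the old
    regime); ``snap="same_month"`` applies it from the budget month.
    """
    if snap not in ("next_month", "same_month"):
        raise TaxError(f"unknown snap convention: {snap!r}")
    offset = 1 if snap == "next_month" else 0
    regimes = []
    for i, (date, fm, ryo, met, label) in enumerate(_UK_ROWS):
        eff = to_index(date, month0) + (0 if i == 0 else offset)
        regimes.append(TaxRegime(effective_month=eff,
                                 specific_fm_per_1000=fm,
                                 specific_ryo_per_kg=ryo,
                                 met_per_1000=met,
                                 label=label))
    return regimes


def regime_for(month: int, timeline: Sequence[TaxRegime]) -> TaxRegime:
    """Latest regime with ``effective_month <= month``."""
    if not timeline:
        raise TaxError("empty regime timeline")
    ordered = sorted(timeline, key=lambda r: r.effective_month)
    if month < ordered[0].effective_month:
        raise TaxError(
            f"month {month} precedes the first regime "
            f"(effective {ordered[0].effective_month})")
    chosen = ordered[0]
    for reg in ordered:
        if reg.effective_month <= month:
            chosen = reg
    return chosen


def sticks_per_pack(product_type: str,
                    pack_sticks: float | None = None,
                    pack_grams: float | None = None,
                    grams_per_stick: float = GRAMS_PER_STICK) -> float:
    """Pack content in sticks (FM) or stick equivalents (RYO).

    Exactly one of ``pack_sticks`` / ``pack_grams`` must be present, matching
    the product type.  RYO stick equivalents may be non-integer.
    """
    has_sticks = pack_sticks is not None and not pd.isna(pack_sticks)
    has_grams = pack_grams is not None and not pd.isna(pack_grams)
    if product_type == "FM":
        if not has_sticks or has_grams:
            raise TaxError("FM records need pack_sticks and no pack_grams")
        return float(pack_sticks)
    if product_type == "RYO":
        if not has_grams or has_sticks:
            raise TaxError("RYO records need pack_grams and no pack_sticks")
        return float(pack_grams) / grams_per_stick
    raise TaxError(f"unknown product type {product_type!r}")


def excise_per_1000(product_type: str,
                    price_per_stick: float,
                    regime: TaxRegime,
                    grams_per_stick: float = GRAMS_PER_STICK
                    ) -> tuple[float, bool]:
    """Total excise duty in GBP per 1,000 sticks, and whether the MET bound.

    FM: the standard computation A = specific + ad_valorem * retail price per
    1,000; with a MET in force the duty is max(A, floor).  RYO: the per-kg
    rate scaled by the stick weight (grams_per_stick grams per stick, i.e.
    1000 * grams_per_stick grams per 1,000 sticks); the MET never applies.
    """
    if product_type == "FM":
        a = regime.specific_fm_per_1000 + regime.advalorem_fm * price_per_stick * 1000.0
        if regime.met_per_1000 is not None:
            return max(a, regime.met_per_1000), regime.met_per_1000 > a
        return a, False
    if product_type == "RYO":
        return regime.specific_ryo_per_kg * grams_per_stick, False
    raise TaxError(f"unknown product type {product_type!r}")


def met_crossover_price_per_1000(regime: TaxRegime) -> float:
    """Retail price per 1,000 sticks at which alternative A meets the MET floor.

    Below this price FM excise is constant at the floor; above it the standard
    specific + ad valorem computation applies.
    """
    if regime.met_per_1000 is None:
        raise TaxError("regime has no MET floor")
    return (regime.met_per_1000 - regime.specific_fm_per_1000) / regime.advalorem_fm


def vat_per_stick(price_per_stick: float, vat_rate: float,
                  vat_mode: str = "exclusive") -> float:
    """VAT content of a per-stick retail price.

    ``"exclusive"`` (default, statutory UK treatment): VAT is ``vat_rate`` of
    the tax-exclusive price, i.e. ``price * r / (1 + r)`` of the gross price.
    ``"gross"``: VAT taken literally as ``vat_rate`` of the gross pack price.
    """
    if vat_mode == "exclusive":
        return price_per_stick * vat_rate / (1.0 + vat_rate)
    if vat_mode == "gross":
        return price_per_stick * vat_rate
    raise TaxError(f"unknown vat_mode {vat_mode!r}")


def tax_breakdown(product_type: str,
                  pack_price_gbp: float,
                  pack_sticks: float | None = None,
                  pack_grams: float | None = None,
                  *,
                  regime: TaxRegime,
                  grams_per_stick: float = GRAMS_PER_STICK,
                  vat_mode: str = "exclusive") -> TaxBreakdown:
    """Per-stick tax decomposition of one pack price under one regime.

    Net revenue is the residual, so price = excise + VAT + net revenue holds
    to machine precision by construction.
    """
    if pack_price_gbp <= 0:
        raise TaxError("pack price must be positive")
    n_sticks = sticks_per_pack(product_type, pack_sticks, pack_grams,
                               grams_per_stick)
    pps = pack_price_gbp / n_sticks
    duty_1000, met_applied = excise_per_1000(product_type, pps, regime,
                                             grams_per_stick)
    excise = duty_1000 / 1000.0
    vat = vat_per_stick(pps, regime.vat_rate, vat_mode)
    net = pps - excise - vat
    if net < 0:
        logger.warning("negative net revenue (%.4f GBP/stick) at price %.4f",
                       net, pps)
    return TaxBreakdown(price_per_stick=pps, excise_per_stick=excise,
                        vat_per_stick=vat, net_revenue_per_stick=net,
                        met_applied=met_applied)


class InflationIndex:
    """Monthly price index, base month = month 1 with value exactly 1.0.

    Deflation divides nominal values by the index, expressing everything in
    base-month (May 2015) money.
    """

    def __init__(self, values: dict[int, float] | pd.Series):
        s = pd.Series(values, dtype=float).sort_index()
        if (s <= 0).any():
            raise TaxError("inflation index values must be strictly positive")
        if 1 in s.index and s.loc[1] != 1.0:
            raise TaxError("inflation index must be exactly 1.0 at the base month")
        self._s = s

    @classmethod
    def flat(cls, n_months: int) -> "InflationIndex":
        """No-inflation index (real == nominal)."""
        return cls({m: 1.0 for m in range(1, n_months + 1)})

    @classmethod
    def from_annual_rate(cls, n_months: int, annual_pct: float) -> "InflationIndex":
        """Geometric index growing at ``annual_pct`` percent per 12 months."""
        monthly = (1.0 + annual_pct / 100.0) ** (1.0 / 12.0)
        return cls({m: monthly ** (m - 1) for m in range(1, n_months + 1)})

    @classmethod
    def from_csv(cls, path) -> "InflationIndex":
        df = pd.read_csv(path)
        if not {"month", "index"} <= set(df.columns):
            raise TaxError("inflation index CSV needs columns: month, index")
        return cls(dict(zip(df["month"].astype(int), df["index"].astype(float))))

    def to_csv(self, path) -> None:
        pd.DataFrame({"month": self._s.index, "index": self._s.values}
                     ).to_csv(path, index=False)

    def __contains__(self, month: int) -> bool:
        return int(month) in self._s.index

    def __getitem__(self, month: int) -> float:
        try:
            return float(self._s.loc[int(month)])
        except KeyError:
            raise TaxError(f"month {month} not in inflation index") from None

    def series(self) -> pd.Series:
        return self._s.copy()


def deflate(value: float, month: int, index: InflationIndex) -> float:
    """Nominal GBP -> real (base-month) GBP."""
    return value / index[month]


def attach_tax_columns(df: pd.DataFrame,
                       timeline: Sequence[TaxRegime],
                       index: InflationIndex | None = None,
                       grams_per_stick: float = GRAMS_PER_STICK,
                       vat_mode: str = "exclusive") -> pd.DataFrame:
    """Vectorised per-record tax decomposition plus real-terms conversion.

    Adds columns: sticks_per_pack, pps_nominal, excise_per_stick,
    vat_per_stick, netrev_nominal, met_applied, and (deflated) pps_real,
    netrev_real.  Taxes are computed on nominal prices first; deflation is
    applied to the resulting price and net revenue only.
    """
    out = df.copy()
    is_fm = out["product_type"].to_numpy() == "FM"
    is_ryo = out["product_type"].to_numpy() == "RYO"
    if not np.all(is_fm | is_ryo):
        bad = out.loc[~(is_fm | is_ryo), "product_type"].unique()
        raise TaxError(f"unknown product types: {list(bad)}")

    n_sticks = np.where(is_fm,
                        out.get("pack_sticks", pd.Series(np.nan, index=out.index)).to_numpy(dtype=float),
                        out.get("pack_grams", pd.Series(np.nan, index=out.index)).to_numpy(dtype=float) / grams_per_stick)
    if np.any(~np.isfinite(n_sticks)) or np.any(n_sticks <= 0):
        raise TaxError("pack content missing or non-positive for some records")
    pps = out["pack_price_gbp"].to_numpy(dtype=float) / n_sticks

    months = out["month"].to_numpy(dtype=int)
    excise = np.empty(len(out))
    met_applied = np.zeros(len(out), dtype=bool)
    vat_rate = np.empty(len(out))
    for m in np.unique(months):
        reg = regime_for(int(m), timeline)
        sel = months == m
        vat_rate[sel] = reg.vat_rate
        a = reg.specific_fm_per_1000 + reg.advalorem_fm * pps[sel] * 1000.0
        if reg.met_per_1000 is not None:
            met = np.maximum(a, reg.met_per_1000)
            met_applied[sel] = is_fm[sel] & (reg.met_per_1000 > a)
        else:
            met = a
        duty_1000 = np.where(is_fm[sel], met,
                             reg.specific_ryo_per_kg * grams_per_stick)
        excise[sel] = duty_1000 / 1000.0

    if vat_mode == "exclusive":
        vat = pps * vat_rate / (1.0 + vat_rate)
    elif vat_mode == "gross":
        vat = pps * vat_rate
    else:
        raise TaxError(f"unknown vat_mode {vat_mode!r}")
    net = pps - excise - vat

    out["sticks_per_pack"] = n_sticks
    out["pps_nominal"] = pps
    out["excise_per_stick"] = excise
    out["vat_per_stick"] = vat
    out["netrev_nominal"] = net
    out["met_applied"] = met_applied

    if index is None:
        deflator = np.ones(len(out))
    else:
        idx = index.series()
        missing = set(np.unique(months)) - set(idx.index)
        if missing:
            raise TaxError(f"months missing from inflation index: {sorted(missing)}")
        deflator = idx.loc[months].to_numpy(dtype=float)
    out["pps_real"] = pps / deflator
    out["netrev_real"] = net / deflator
    return out


def timeline_from_dicts(rows: Iterable[dict]) -> list[TaxRegime]:
    """Regime timeline from config mappings (one per regime row)."""
    regimes = [TaxRegime(**row) for row in rows]
    ordered = sorted(regimes, key=lambda r: r.effective_month)
    for a, b in zip(ordered, ordered[1:]):
        if a.effective_month == b.effective_month:
            raise TaxError(f"overlapping regimes at month {a.effective_month}")
    return ordered
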