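"""Synthetic SKU-level monthly sales panels.

Generates seeded panels with the statistical structure the trend analysis
assumes: eight market segments (four FM, three RYO, plus "no segment"),
eleven geographies with fixed level offsets but a common trend shape,
segment-specific smooth nonlinear time trends, strong within-series AR1
price noise (default rho = 0.98), right-skewed (lognormal) sales volumes,
and tax-event price jumps with configurable per-segment pass-through
(fractions below 1 construct undershifting ground truth, above 1
overshifting).

Per-stick price for SKU s of segment k in geography j at month t:

    pps[s,j,t] = base_k + trend_k(t) + geo_j + sum(jumps up to t) + e[s,j,t]

with e a stationary AR1(rho) process with innovation sd sigma_eps.  Trends
are monotone-cubic interpolations of (month, offset) knots, so they are
smooth in the sense the spline model assumes.  Volumes are drawn lognormal
and are independent of price (no demand response is simulated).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

logger = logging.getLogger(__name__)

SEGMENT_NAMES = (
    "FM premium", "FM midprice", "FM value", "FM subvalue",
    "RYO premium", "RYO midprice", "RYO value", "no segment",
)

DEFAULT_GEOGRAPHIES = (
    "London", "Midlands", "North West England", "Yorkshire",
    "North East England", "South & South East", "West & South West",
    "East of England", "Wales", "Scotland", "Northern Ireland",
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentSpec:
    """One market segment: how many SKUs, their price level, trend and packs.

    ``trend_knots`` are (month, offset GBP/stick) pairs interpolated with a
    monotone cubic; an empty list means a flat trend.  ``pack_sizes`` are
    sticks for FM, grams for RYO.
    """

    name: str
    product_type: str
    n_skus: int
    base_price_per_stick: float
    trend_knots: tuple = ()
    pack_sizes: tuple = (20,)

    def __post_init__(self):
        if self.product_type not in ("FM", "RYO"):
            raise ConfigError(f"segment {self.name!r}: product_type must be FM or RYO")
        if self.n_skus < 1:
            raise ConfigError(f"segment {self.name!r}: n_skus must be >= 1")
        if self.base_price_per_stick <= 0:
            raise ConfigError(f"segment {self.name!r}: base_price_per_stick must be > 0")
        if not self.pack_sizes:
            raise ConfigError(f"segment {self.name!r}: pack_sizes must be non-empty")

    def trend(self, months: np.ndarray) -> np.ndarray:
        if not self.trend_knots:
            return np.zeros(len(months))
        kx = np.array([m for m, _ in self.trend_knots], dtype=float)
        ky = np.array([v for _, v in self.trend_knots], dtype=float)
        if len(kx) == 1:
            return np.full(len(months), ky[0])
        if np.any(np.diff(kx) <= 0):
            raise ConfigError(f"segment {self.name!r}: trend knot months must increase")
        return PchipInterpolator(kx, ky, extrapolate=True)(months)


@dataclass(frozen=True)
class TaxEventSpec:
    """A duty rise embedded at generation time.

    ``month`` is the first month at which prices reflect the change (for a
    mid-month budget this is the month after the budget).  Pass-through maps
    segment name -> fraction of the per-stick duty increase added to price.
    """

    month: int
    duty_increase_per_stick: float
    passthrough: Mapping[str, float]


def default_segments() -> tuple[SegmentSpec, ...]:
    """Eight UK-style segments with May-2015-realistic per-stick base prices.

    FM prices bracket roughly GBP 6-9.30 per 20-pack; RYO stick equivalents
    (0.5 g) are much cheaper.  A gentle upward nonlinear trend of about 1-2p
    over three years mirrors the scale of observed real price movement.
    """
    gentle = ((1, 0.0), (12, 0.004), (24, 0.007), (36, 0.015))
    return (
        SegmentSpec("FM premium", "FM", 25, 0.465, gentle, (20, 10)),
        SegmentSpec("FM midprice", "FM", 25, 0.405, gentle, (20, 10)),
        SegmentSpec("FM value", "FM", 25, 0.345, gentle, (20,)),
        SegmentSpec("FM subvalue", "FM", 25, 0.305, gentle, (20, 18)),
        SegmentSpec("RYO premium", "RYO", 25, 0.205, gentle, (12.5, 25, 50)),
        SegmentSpec("RYO midprice", "RYO", 25, 0.185, gentle, (12.5, 25)),
        SegmentSpec("RYO value", "RYO", 25, 0.165, gentle, (12.5, 30, 50)),
        SegmentSpec("no segment", "RYO", 25, 0.175, gentle, (30,)),
    )


@dataclass(frozen=True)
class PanelConfig:
    n_months: int = 36
    month0: str = "2015-05"
    geographies: tuple = DEFAULT_GEOGRAPHIES
    segments: tuple = field(default_factory=default_segments)
    seed: int = 0
    tax_events: tuple = ()
    rho: float = 0.98
    sigma_eps: float = 0.002
    volume_log_mean: float = 10.0
    volume_log_sd: float = 1.0
    volume_month_sd: float = 0.2
    geo_offsets: tuple | None = None
    low_distribution_frac: float = 0.10
    missing_distribution_frac: float = 0.002
    churn_frac: float = 0.10
    sku_level_sd: float = 0.0
    unmapped_fraction: float = 0.0

    def __post_init__(self):
        if self.n_months < 2:
            raise ConfigError("n_months must be >= 2")
        if not (-1.0 < self.rho < 1.0):
            raise ConfigError("rho must satisfy |rho| < 1")
        if self.sigma_eps < 0:
            raise ConfigError("sigma_eps must be >= 0")
        if not self.geographies:
            raise ConfigError("geographies must be non-empty")
        if not self.segments:
            raise ConfigError("segments must be non-empty")
        if self.geo_offsets is not None and len(self.geo_offsets) != len(self.geographies):
            raise ConfigError("geo_offsets must match geographies in length")
        if self.volume_month_sd < 0:
            raise ConfigError("volume_month_sd must be >= 0")
        for frac in ("low_distribution_frac", "missing_distribution_frac",
                     "churn_frac", "unmapped_fraction"):
            if not (0.0 <= getattr(self, frac) <= 1.0):
                raise ConfigError(f"{frac} must lie in [0, 1]")
        for ev in self.tax_events:
            if not (1 <= ev.month <= self.n_months):
                raise ConfigError(f"tax event month {ev.month} outside panel range")
            for seg, f in ev.passthrough.items():
                if f < 0:
                    raise ConfigError(f"pass-through for {seg!r} must be >= 0")
        _check_price_ordering(self.segments)


def _check_price_ordering(segments: Sequence[SegmentSpec]) -> None:
    """Premium > midprice > value > subvalue within each product type."""
    order = ["premium", "midprice", "value", "subvalue"]
    for ptype in ("FM", "RYO"):
        tiers = {}
        for s in segments:
            low = s.name.lower()
            if s.name == "no segment" or s.product_type != ptype:
                continue
            for tier in order:
                if tier in low and not (tier == "value" and "subvalue" in low):
                    tiers[tier] = s.base_price_per_stick
                    break
        prices = [tiers[t] for t in order if t in tiers]
        if any(a <= b for a, b in zip(prices, prices[1:])):
            raise ConfigError(
                f"{ptype} segment base prices must decrease premium > midprice "
                f"> value > subvalue")


def _geo_offsets(config: PanelConfig) -> np.ndarray:
    if config.geo_offsets is not None:
        return np.asarray(config.geo_offsets, dtype=float)
    n = len(config.geographies)
    return np.linspace(-0.01, 0.01, n)


def generate_panel(config: PanelConfig) -> pd.DataFrame:
    """One record per SKU x geography x month (minus churned records).

    Deterministic for a given config: per-SKU random substreams are spawned
    from the root seed, so adding a segment does not disturb the draws of
    existing ones.
    """
    months = np.arange(1, config.n_months + 1)
    geo_off = _geo_offsets(config)
    n_geo = len(config.geographies)
    root = np.random.SeedSequence(config.seed)

    # cumulative tax-event jump per segment per month
    jumps = {}
    for seg in config.segments:
        j = np.zeros(config.n_months)
        for ev in config.tax_events:
            if seg.name not in ev.passthrough:
                raise ConfigError(
                    f"tax event at month {ev.month}: no pass-through for "
                    f"segment {seg.name!r}")
            j[ev.month - 1:] += ev.duty_increase_per_stick * ev.passthrough[seg.name]
        jumps[seg.name] = j

    frames = []
    sku_counter = 0
    for seg in config.segments:
        trend = seg.trend(months.astype(float))
        for i in range(seg.n_skus):
            ss = np.random.SeedSequence(entropy=config.seed,
                                        spawn_key=(sku_counter,))
            rng = np.random.default_rng(ss)
            sku_id = f"SKU{sku_counter:05d}"
            variant = f"{seg.name} variant {i:03d}"
            pack = seg.pack_sizes[i % len(seg.pack_sizes)]
            sku_off = rng.normal(0.0, config.sku_level_sd) if config.sku_level_sd > 0 else 0.0
            # stationary AR1 noise, one path per geography
            if config.sigma_eps > 0:
                sig_marg = config.sigma_eps / np.sqrt(1.0 - config.rho ** 2)
                e = np.empty((n_geo, config.n_months))
                e[:, 0] = rng.normal(0.0, sig_marg, n_geo)
                innov = rng.normal(0.0, config.sigma_eps,
                                   (n_geo, config.n_months - 1))
                for t in range(1, config.n_months):
                    e[:, t] = config.rho * e[:, t - 1] + innov[:, t - 1]
            else:
                e = np.zeros((n_geo, config.n_months))

            # entry/exit churn: truncate the series for some SKUs
            start, end = 1, config.n_months
            if config.churn_frac > 0 and rng.random() < config.churn_frac:
                if rng.random() < 0.5:
                    start = int(rng.integers(2, max(3, config.n_months // 3)))
                else:
                    end = int(rng.integers(2 * config.n_months // 3,
                                           config.n_months))
            keep = (months >= start) & (months <= end)

            low_dist = rng.random() < config.low_distribution_frac
            pps = (seg.base_price_per_stick + sku_off + trend[None, :]
                   + geo_off[:, None] + jumps[seg.name][None, :] + e)
            sticks = pack if seg.product_type == "FM" else pack / 0.5
            # volumes: a persistent lognormal level per (SKU, geography) with
            # modest month-to-month jitter, so market shares are right-skewed
            # across SKUs but stable in time, as in real sales panels
            level = rng.normal(config.volume_log_mean, config.volume_log_sd,
                               (n_geo, 1))
            jitter = rng.normal(0.0, config.volume_month_sd,
                                (n_geo, config.n_months))
            vol = np.exp(level + jitter)
            if low_dist:
                dist = rng.uniform(2.0, 9.5, (n_geo, config.n_months))
            else:
                dist = rng.uniform(10.0, 95.0, (n_geo, config.n_months))
            miss = rng.random((n_geo, config.n_months)) < config.missing_distribution_frac
            dist = np.where(miss, np.nan, dist)

            gi, ti = np.meshgrid(np.arange(n_geo), np.arange(config.n_months),
                                 indexing="ij")
            keep2 = keep[None, :] & np.ones((n_geo, 1), dtype=bool)
            frames.append(pd.DataFrame({
                "sku_id": sku_id,
                "brand_variant": variant,
                "product_type": seg.product_type,
                "segment": seg.name,
                "geography": np.asarray(config.geographies)[gi[keep2]],
                "month": months[ti[keep2] % config.n_months][...],
                "pack_price_gbp": (pps * sticks)[keep2],
                "pack_sticks": float(pack) if seg.product_type == "FM" else np.nan,
                "pack_grams": float(pack) if seg.product_type == "RYO" else np.nan,
                "volume_sticks": np.round(vol[keep2]),
                "distribution_pct": dist[keep2],
            }))
            sku_counter += 1
    panel = pd.concat(frames, ignore_index=True)
    panel["month"] = panel["month"].astype(int)
    return panel.sort_values(["sku_id", "geography", "month"],
                             kind="mergesort").reset_index(drop=True)


def embed_tax_event(panel: pd.DataFrame, month: int,
                    duty_increase_per_stick: float,
                    passthrough_by_segment: Mapping[str, float]) -> pd.DataFrame:
    """Add a duty-rise price jump to an existing panel, from ``month`` onward.

    Each record's nominal pack price rises by
    ``duty_increase_per_stick * passthrough[segment] * sticks_per_pack``.
    """
    if not (panel["month"].min() <= month <= panel["month"].max()):
        raise ConfigError(f"event month {month} outside panel range")
    segs = set(panel["segment"].unique())
    unknown = set(passthrough_by_segment) - segs
    if unknown:
        raise ConfigError(f"unknown segment keys in pass-through map: {sorted(unknown)}")
    missing = segs - set(passthrough_by_segment)
    if missing:
        raise ConfigError(f"pass-through map missing segments: {sorted(missing)}")
    out = panel.copy()
    sticks = np.where(out["product_type"].to_numpy() == "FM",
                      out["pack_sticks"].to_numpy(dtype=float),
                      out["pack_grams"].to_numpy(dtype=float) / 0.5)
    theta = out["segment"].map(passthrough_by_segment).to_numpy(dtype=float)
    bump = duty_increase_per_stick * theta * sticks
    sel = out["month"].to_numpy() >= month
    out.loc[sel, "pack_price_gbp"] = out.loc[sel, "pack_price_gbp"] + bump[sel]
    return out


def segment_map_frame(config: PanelConfig) -> pd.DataFrame:
    """brand_variant -> segment mapping implied by the generator.

    Variants of the "no segment" segment, plus a configurable fraction of
    others (``unmapped_fraction``, removed deterministically), are left out of
    the map so that downstream assignment exercises the "no segment" default.
    """
    rows = []
    for seg in config.segments:
        if seg.name == "no segment":
            continue
        for i in range(seg.n_skus):
            rows.append((f"{seg.name} variant {i:03d}", seg.name))
    df = pd.DataFrame(rows, columns=["brand_variant", "segment"])
    if config.unmapped_fraction > 0 and len(df):
        n_drop = int(round(config.unmapped_fraction * len(df)))
        df = df.iloc[: len(df) - n_drop]
    return df


def config_from_dict(d: dict) -> PanelConfig:
    """Build a PanelConfig from plain (e.g. YAML-loaded) mappings."""
    d = dict(d)
    if "segments" in d:
        segs = []
        for s in d["segments"]:
            s = dict(s)
            if "trend_knots" in s:
                s["trend_knots"] = tuple((int(m), float(v)) for m, v in s["trend_knots"])
            if "pack_sizes" in s:
                s["pack_sizes"] = tuple(s["pack_sizes"])
            segs.append(SegmentSpec(**s))
        d["segments"] = tuple(segs)
    if "tax_events" in d:
        d["tax_events"] = tuple(
            TaxEventSpec(month=int(ev["month"]),
                         duty_increase_per_stick=float(ev["duty_increase_per_stick"]),
                         passthrough=dict(ev["passthrough"]))
            for ev in d["tax_events"])
    for key in ("geographies", "geo_offsets"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return PanelConfig(**d)


def with_overrides(config: PanelConfig, **kw) -> PanelConfig:
    return replace(config, **kw)
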