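"""Panel CSV reading, inclusion rules and segment assignment.

Inclusion rules mirror standard EPOS practice for widely distributed
products: monthly observations with missing distribution information are
excluded, and a (SKU, month) must be stocked by at least 10% of retailers
-- judged both at UK level (volume-weighted across geographies) and within
each geography -- to enter the analysis.

Segment labels are attached from an exact-string brand-variant map;
unmapped variants fall into the "no segment" category.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NO_SEGMENT = "no segment"

PANEL_COLUMNS = [
    "sku_id", "brand_variant", "product_type", "segment", "geography",
    "month", "pack_price_gbp", "pack_sticks", "pack_grams",
    "volume_sticks", "distribution_pct",
]

REQUIRED_COLUMNS = [c for c in PANEL_COLUMNS if c != "segment"]


class SchemaError(ValueError):
    pass


def _validate_rows(df: pd.DataFrame) -> pd.Series:
    """Reason string per invalid row, empty string when valid."""
    reason = pd.Series("", index=df.index, dtype=object)
    price = pd.to_numeric(df["pack_price_gbp"], errors="coerce")
    vol = pd.to_numeric(df["volume_sticks"], errors="coerce")
    month = pd.to_numeric(df["month"], errors="coerce")
    sticks = pd.to_numeric(df["pack_sticks"], errors="coerce")
    grams = pd.to_numeric(df["pack_grams"], errors="coerce")
    ptype = df["product_type"].astype(str)

    reason[~ptype.isin(["FM", "RYO"])] = "unknown product_type"
    reason[(reason == "") & (price.isna() | (price <= 0))] = "non-positive or missing price"
    reason[(reason == "") & (vol.isna() | (vol < 0))] = "negative or missing volume"
    reason[(reason == "") & (month.isna() | (month < 1))] = "invalid month"
    fm_bad = (ptype == "FM") & (sticks.isna() | ~grams.isna())
    ryo_bad = (ptype == "RYO") & (grams.isna() | ~sticks.isna())
    reason[(reason == "") & (fm_bad | ryo_bad)] = "pack content inconsistent with product_type"
    return reason


def read_panel(path, on_invalid: str = "drop") -> pd.DataFrame:
    """Read a panel CSV into typed records.

    Rows violating the record invariants (non-positive price, negative
    volume, pack content inconsistent with product type, bad month) are
    dropped (``on_invalid="drop"``, default) or raise (``"raise"``); the
    offending rows, with their 1-based CSV line numbers and a reason, are
    logged and kept in ``df.attrs["invalid_rows"]``.
    """
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"panel CSV missing required columns: {sorted(missing)}")
    if "segment" not in df.columns:
        df["segment"] = NO_SEGMENT
    reason = _validate_rows(df)
    bad = reason != ""
    invalid = df.loc[bad].copy()
    invalid["line"] = invalid.index + 2  # header is line 1
    invalid["reason"] = reason[bad]
    if bad.any():
        for _, row in invalid.head(20).iterrows():
            logger.warning("rejected line %d: %s", row["line"], row["reason"])
        if on_invalid == "raise":
            raise SchemaError(f"{bad.sum()} invalid rows (first: "
                              f"line {invalid['line'].iloc[0]}, "
                              f"{invalid['reason'].iloc[0]})")
    out = df.loc[~bad].copy()
    out["month"] = out["month"].astype(int)
    for col in ("pack_price_gbp", "pack_sticks", "pack_grams",
                "volume_sticks", "distribution_pct"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    out = out.reset_index(drop=True)
    out.attrs["invalid_rows"] = invalid
    return out


def write_panel(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in PANEL_COLUMNS if c in df.columns])


@dataclass(frozen=True)
class SegmentMap:
    """Exact-string brand_variant -> segment mapping."""

    mapping: Mapping[str, str]

    @classmethod
    def from_csv(cls, path) -> "SegmentMap":
        df = pd.read_csv(path)
        if not {"brand_variant", "segment"} <= set(df.columns):
            raise SchemaError("segment map CSV needs columns: brand_variant, segment")
        return cls(dict(zip(df["brand_variant"], df["segment"])))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SegmentMap":
        return cls(dict(zip(df["brand_variant"], df["segment"])))

    def get(self, variant: str) -> str:
        return self.mapping.get(variant, NO_SEGMENT)


def assign_segments(df: pd.DataFrame, seg_map: SegmentMap) -> pd.DataFrame:
    """Attach segment labels; unmapped variants become "no segment"."""
    out = df.copy()
    out["segment"] = out["brand_variant"].map(seg_map.mapping).fillna(NO_SEGMENT)
    n_unmapped = int((out["segment"] == NO_SEGMENT).sum())
    if n_unmapped:
        logger.info("%d records assigned to %r", n_unmapped, NO_SEGMENT)
    return out


@dataclass(frozen=True)
class FilterResult:
    kept: pd.DataFrame
    n_dropped_missing: int
    n_dropped_below: int

    @property
    def n_input(self) -> int:
        return len(self.kept) + self.n_dropped_missing + self.n_dropped_below


def apply_distribution_filter(df: pd.DataFrame,
                              threshold_pct: float = 10.0,
                              uk_level: bool = True) -> FilterResult:
    """Keep widely distributed (SKU, month) observations.

    Records with missing distribution are dropped first.  A (SKU, month) is
    then dropped *everywhere* if its UK-level distribution (volume-weighted
    across geographies) is below the threshold, and an individual (SKU,
    month, geography) row is dropped if its own distribution is below the
    threshold.  The threshold is inclusive: distribution exactly at the
    threshold is kept.  kept + dropped_missing + dropped_below equals the
    input count.
    """
    dist = pd.to_numeric(df["distribution_pct"], errors="coerce")
    missing = dist.isna()
    n_missing = int(missing.sum())
    present = df.loc[~missing].copy()
    dist_p = dist[~missing]

    below = dist_p < threshold_pct
    if uk_level and len(present):
        vol = present["volume_sticks"].to_numpy(dtype=float)
        w = np.where(vol > 0, vol, 1.0)  # unweighted fallback for zero-volume rows
        key = pd.MultiIndex.from_frame(present[["sku_id", "month"]])
        num = pd.Series(dist_p.to_numpy() * w, index=key).groupby(level=[0, 1]).sum()
        den = pd.Series(w, index=key).groupby(level=[0, 1]).sum()
        uk_dist = (num / den).reindex(key).to_numpy()
        below = below | (uk_dist < threshold_pct)

    kept = present.loc[~below.to_numpy()].reset_index(drop=True)
    n_below = int(below.sum())
    logger.info("distribution filter: kept %d, dropped %d missing, %d below %.1f%%",
                len(kept), n_missing, n_below, threshold_pct)
    return FilterResult(kept=kept, n_dropped_missing=n_missing,
                        n_dropped_below=n_below)
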