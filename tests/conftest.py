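import numpy as np
import pandas as pd
import pytest

from tobtax.panel import PanelConfig, SegmentSpec, generate_panel


def add_pps(df: pd.DataFrame) -> pd.DataFrame:
    """Attach per-stick price (no taxes, no deflation) for model tests."""
    out = df.copy()
    sticks = np.where(out["product_type"] == "FM",
                      out["pack_sticks"], out["pack_grams"] / 0.5)
    out["pps_real"] = out["pack_price_gbp"] / sticks
    return out


def small_config(**overrides) -> PanelConfig:
    """Three-segment, three-geography panel small enough for fast fits."""
    base = dict(
        n_months=36,
        geographies=("North", "Mid", "South"),
        segments=(
            SegmentSpec("FM premium", "FM", 6, 0.46),
            SegmentSpec("FM value", "FM", 6, 0.34),
            SegmentSpec("RYO value", "RYO", 6, 0.16, pack_sizes=(30.0,)),
        ),
        seed=7,
        rho=0.9,
        sigma_eps=0.002,
        churn_frac=0.0,
        low_distribution_frac=0.0,
        missing_distribution_frac=0.0,
    )
    base.update(overrides)
    return PanelConfig(**base)


@pytest.fixture(scope="session")
def small_panel():
    return generate_panel(small_config())


@pytest.fixture(scope="session")
def small_panel_pps(small_panel):
    return add_pps(small_panel)
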