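"""Weighted series, gaps, growth windows, shifting classification."""
import numpy as np
import pandas as pd
import pytest

from tobtax import summaries, tax
from tobtax.model import ModelSpec, TrendModel
from tobtax.panel import PanelConfig, SegmentSpec, generate_panel
from tobtax.summaries import (WeightedSeries, classify_shift, gap_series,
                              growth_comparison, observed_weighted_series,
                              shift_analysis, weighted_average_series,
                              window_growth)
from tests.conftest import add_pps, small_config


@pytest.fixture(scope="module")
def fitted():
    df = add_pps(generate_panel(small_config(seed=13)))
    res = TrendModel(df, spec=ModelSpec(basis_dim=8)).fit()
    draws = res.simulate_params(800, seed=2)
    return df, res, draws


def series_from(months, draws):
    est = draws.mean(axis=1)
    return WeightedSeries("test", "s", np.asarray(months), est,
                          lo=np.quantile(draws, 0.025, axis=1),
                          hi=np.quantile(draws, 0.975, axis=1), draws=draws)


class TestWeightedAverage:
    def test_two_sku_weighted_mean_arithmetic(self):
        df = pd.DataFrame({
            "sku_id": ["a", "b"], "product_type": ["FM", "FM"],
            "segment": ["FM value", "FM value"], "geography": ["G", "G"],
            "month": [1, 1], "volume_sticks": [1000.0, 3000.0],
            "pps": [0.40, 0.20],
        })
        out = observed_weighted_series(df, "pps", "overall")["all"]
        assert out.estimate[0] == pytest.approx(0.25)

    def test_identical_modelled_prices_give_zero_width(self, fitted):
        df, res, _ = fitted
        draws0 = np.repeat(res.params[None, :], 50, axis=0)  # zero covariance
        ser = weighted_average_series(res, df, draws0, "overall")["all"]
        assert np.allclose(ser.hi - ser.lo, 0.0, atol=1e-12)

    def test_estimate_between_min_and_max_modelled_price(self, fitted):
        df, res, draws = fitted
        ser = weighted_average_series(res, df, draws, "segment")
        pred = res.predict(df)
        for seg, s in ser.items():
            sel = df["segment"] == seg
            for m, est in zip(s.months, s.estimate):
                sub = pred[(sel & (df["month"] == m)).to_numpy()]
                assert sub.min() - 1e-3 <= est <= sub.max() + 1e-3

    def test_wap_tracks_generating_trend(self):
        # strong known trend; the modelled WAP interval should cover the
        # volume-weighted generating mean in at least 90% of months
        trend = ((1, 0.0), (12, 0.02), (24, -0.01), (36, 0.03))
        cfg = small_config(seed=29, segments=(
            SegmentSpec("FM value", "FM", 8, 0.34, trend),))
        df = add_pps(generate_panel(cfg))
        res = TrendModel(df, spec=ModelSpec(basis_dim=10)).fit()
        draws = res.simulate_params(500, seed=3)
        ser = weighted_average_series(res, df, draws, "overall")["all"]
        geo_off = dict(zip(cfg.geographies, np.linspace(-0.01, 0.01, 3)))
        true_pps = (0.34 + cfg.segments[0].trend(df["month"].to_numpy(float))
                    + df["geography"].map(geo_off).to_numpy())
        df2 = df.assign(true_pps=true_pps)
        truth = observed_weighted_series(df2, "true_pps", "overall")["all"]
        cover = np.mean((ser.lo <= truth.estimate) & (truth.estimate <= ser.hi))
        assert cover >= 0.90

    def test_conservation_across_tax_components(self, fitted):
        # WAP(price) - WAP(excise) - WAP(VAT) = WAP(net revenue) with shared
        # weights, month by month
        df, _, _ = fitted
        taxed = tax.attach_tax_columns(df, tax.uk_timeline())
        parts = {c: observed_weighted_series(taxed, c, "overall")["all"]
                 for c in ("pps_nominal", "excise_per_stick", "vat_per_stick",
                           "netrev_nominal")}
        lhs = (parts["pps_nominal"].estimate - parts["excise_per_stick"].estimate
               - parts["vat_per_stick"].estimate)
        assert np.allclose(lhs, parts["netrev_nominal"].estimate, atol=1e-12)


class TestGaps:
    def test_identical_strata_zero_gap(self, fitted):
        df, res, draws = fitted
        s = weighted_average_series(res, df, draws, "segment")["FM premium"]
        g = gap_series(s, s)
        assert np.allclose(g.estimate, 0.0, atol=1e-12)

    def test_antisymmetry(self, fitted):
        df, res, draws = fitted
        ser = weighted_average_series(res, df, draws, "segment")
        g1 = gap_series(ser["FM premium"], ser["FM value"])
        g2 = gap_series(ser["FM value"], ser["FM premium"])
        assert np.allclose(g1.estimate, -g2.estimate, atol=1e-12)

    def test_constant_offset_recovered(self, fitted):
        df, res, draws = fitted
        ser = weighted_average_series(res, df, draws, "segment")
        g = gap_series(ser["FM premium"], ser["FM value"])
        # generator base prices differ by 0.12 GBP/stick with common trend;
        # per-month gaps wobble with the AR1 noise, the average does not
        assert g.estimate.mean() == pytest.approx(0.12, abs=0.005)
        assert np.allclose(g.estimate, 0.12, atol=0.02)

    def test_correlated_differencing_no_wider_than_independent(self, fitted):
        df, res, draws = fitted
        ser = weighted_average_series(res, df, draws, "segment")
        a, b = ser["FM premium"], ser["FM value"]
        g = gap_series(a, b)
        width = g.hi - g.lo
        rng = np.random.default_rng(0)
        perm = rng.permutation(b.draws.shape[1])
        indep = a.draws - b.draws[:, perm]
        width_indep = (np.quantile(indep, 0.975, axis=1)
                       - np.quantile(indep, 0.025, axis=1))
        assert width.mean() <= width_indep.mean() * 1.05


class TestWindowGrowth:
    def test_linear_series_slope(self):
        months = np.arange(1, 13)
        draws = np.repeat((0.001 * months)[:, None], 10, axis=1)
        g = window_growth(series_from(months, draws), (1, 11))
        assert g.estimate == pytest.approx(0.001, abs=1e-12)

    def test_flat_series_zero(self):
        months = np.arange(1, 13)
        draws = np.full((12, 10), 0.3)
        g = window_growth(series_from(months, draws), (2, 11))
        assert g.estimate == 0.0

    def test_short_window_rejected(self):
        months = np.arange(1, 13)
        draws = np.full((12, 10), 0.3)
        with pytest.raises(ValueError):
            window_growth(series_from(months, draws), (3, 3))

    def test_pre_post_difference_detected(self):
        # flat for 12 months then rising 0.5p/month: the post-pre growth
        # difference interval excludes zero
        rng = np.random.default_rng(5)
        months = np.arange(1, 25)
        level = np.where(months <= 12, 0.30, 0.30 + 0.005 * (months - 12))
        draws = level[:, None] + rng.normal(0, 2e-4, (24, 400))
        comp = growth_comparison(series_from(months, draws),
                                 window_pre=(1, 12), window_post=(13, 24))
        assert comp.diff_lo > 0

    def test_unequal_windows_rejected(self):
        months = np.arange(1, 25)
        draws = np.full((24, 10), 0.3)
        with pytest.raises(ValueError, match="equal length"):
            growth_comparison(series_from(months, draws), (1, 5), (6, 20))


class TestShiftClassification:
    def test_classification_rule(self):
        assert classify_shift(-2.0, -0.5) == "undershift"
        assert classify_shift(0.5, 2.0) == "overshift"
        assert classify_shift(-0.5, 0.5) == "indeterminate"

    def test_matches_bruteforce_ci_sign_oracle(self):
        rng = np.random.default_rng(11)
        months = np.arange(1, 13)
        draws = 0.10 + rng.normal(0, 0.002, (12, 500))
        draws[8:] -= 0.01  # clear net revenue fall after month 8
        ser = {"seg": series_from(months, draws)}
        table = shift_analysis(ser, event_month=6, horizons=(1, 2, 3, 4, 5))
        for _, row in table.iterrows():
            d = (ser["seg"].draws[ser["seg"]._index(6 + row["horizon"])]
                 - ser["seg"].draws[ser["seg"]._index(6)]) * 100
            lo, hi = np.quantile(d, [0.025, 0.975])
            expected = ("undershift" if hi < 0 else
                        "overshift" if lo > 0 else "indeterminate")
            assert row["classification"] == expected
        assert (table.loc[table["horizon"] >= 3, "classification"]
                == "undershift").all()

    def test_truncated_horizons_warn(self):
        months = np.arange(1, 13)
        draws = np.full((12, 50), 0.1)
        with pytest.warns(UserWarning, match="truncated"):
            table = shift_analysis({"s": series_from(months, draws)},
                                   event_month=10)
        assert set(table["horizon"]) == {1, 2}
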