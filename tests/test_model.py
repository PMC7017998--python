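"""Additive AR1 trend model: oracles, identifiability, diagnostics."""
import numpy as np
import pandas as pd
import pytest

from tobtax.model import ModelSpec, TrendModel, TrendResults
from tobtax.panel import SegmentSpec, generate_panel
from tests.conftest import add_pps, small_config


def tiny_panel(n_skus=5, n_months=10, seed=0, rho=0.6, sigma=0.01):
    cfg = small_config(
        n_months=n_months,
        geographies=("G1",),
        segments=(SegmentSpec("FM premium", "FM", n_skus, 0.40),
                  SegmentSpec("FM value", "FM", n_skus, 0.30)),
        seed=seed, rho=rho, sigma_eps=sigma)
    return add_pps(generate_panel(cfg))


def manual_whiten(df, X, y, rho):
    """Independent AR1 whitening: explicit per-series loop."""
    Xw, yw = X.astype(float).copy(), y.astype(float).copy()
    df = df.reset_index(drop=True)
    for _, idx in df.groupby(["sku_id", "geography"]).indices.items():
        idx = np.sort(idx)
        months = df.loc[idx, "month"].to_numpy()
        for a, b, g in zip(idx[:-1], idx[1:], np.diff(months)):
            lag = rho ** g
            den = np.sqrt(1 - lag ** 2)
            Xw[b] = (X[b] - lag * X[a]) / den
            yw[b] = (y[b] - lag * y[a]) / den
    return Xw, yw


class TestOracles:
    def test_rho_zero_lambda_zero_equals_ols(self):
        df = tiny_panel()
        model = TrendModel(df, spec=ModelSpec(basis_dim=4))
        res = model.fit(rho=0.0, lambdas=0.0)
        beta, *_ = np.linalg.lstsq(model.exog, model.endog, rcond=None)
        assert np.allclose(res.params, beta, atol=1e-8)

    def test_known_rho_equals_ols_on_whitened_data(self):
        # 50-record panel: GLS with fixed rho must equal plain least squares
        # on explicitly AR1-differenced data
        df = tiny_panel(n_skus=5, n_months=5)
        assert len(df) == 50
        model = TrendModel(df, spec=ModelSpec(basis_dim=4))
        res = model.fit(rho=0.6, lambdas=0.0)
        Xw, yw = manual_whiten(model.data, model.exog, model.endog, 0.6)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        assert np.allclose(res.params, beta, atol=1e-8)

    def test_whitening_handles_gaps_as_rho_power(self):
        df = tiny_panel(n_months=12)
        df = df[~df["month"].isin([4, 5])].reset_index(drop=True)  # gap of 3
        model = TrendModel(df, spec=ModelSpec(basis_dim=4))
        res = model.fit(rho=0.7, lambdas=0.0)
        Xw, yw = manual_whiten(model.data, model.exog, model.endog, 0.7)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        assert np.allclose(res.params, beta, atol=1e-8)

    def test_duplicated_panel_with_scaled_penalty_reproduces_fit(self):
        df = tiny_panel(n_months=12)
        model = TrendModel(df, spec=ModelSpec(basis_dim=6))
        lam = [2.5, 2.5]
        res = model.fit(rho=0.5, lambdas=lam)
        dup = df.copy()
        dup["sku_id"] = dup["sku_id"] + "_copy"
        both = pd.concat([df, dup], ignore_index=True)
        res2 = TrendModel(both, spec=ModelSpec(basis_dim=6)).fit(
            rho=0.5, lambdas=[2 * l for l in lam])
        assert np.allclose(res.params, res2.params, atol=1e-8)


class TestRecovery:
    def test_flat_trend_smooths_near_zero(self):
        # generated with no trend and rho=0: smooth estimates stay near zero
        df = add_pps(generate_panel(small_config(rho=0.0, sigma_eps=0.003,
                                                 seed=21)))
        res = TrendModel(df).fit(rho=0.0)
        months = np.arange(1, 37)
        covered = 0
        total = 0
        for seg in ("FM premium", "FM value", "RYO value"):
            blk = [b for b in res.design.blocks if b.segment == seg][0]
            B = blk.spline.design(months.astype(float)) @ blk.Z
            f = B @ res.params[blk.sl]
            se = np.sqrt(np.einsum("ij,jk,ik->i", B, res.cov[blk.sl, blk.sl], B))
            covered += int(np.sum(np.abs(f) <= 1.96 * se + 1e-12))
            total += len(months)
        assert covered / total >= 0.90

    def test_rho_recovery_on_small_panel(self):
        df = add_pps(generate_panel(small_config(rho=0.9, seed=23)))
        res = TrendModel(df).fit()
        assert res.rho == pytest.approx(0.9, abs=0.03)

    def test_forcing_rho_zero_leaves_autocorrelated_residuals(self):
        df = add_pps(generate_panel(small_config(rho=0.98, sigma_eps=0.002,
                                                 seed=31)))
        res0 = TrendModel(df).fit(rho=0.0)
        assert res0.raw_lag1_autocorr() > 0.9
        res = TrendModel(df).fit()
        assert abs(res.whitened_lag1_autocorr()) < 0.1

    def test_zero_noise_residuals_vanish(self):
        df = add_pps(generate_panel(small_config(sigma_eps=0.0)))
        res = TrendModel(df).fit(rho=0.0)
        assert np.max(np.abs(res.resid_whitened)) < 1e-8


class TestModelSelection:
    def test_basis_dim_insensitive_on_linear_data(self):
        # the penalty shrinks unused flexibility, so a k=10 smooth on data
        # with a purely linear trend costs about the same AIC as k=4
        from tobtax.panel import generate_panel
        lin = ((1, 0.0), (36, 0.02))
        cfg = small_config(seed=55, segments=(
            SegmentSpec("FM premium", "FM", 6, 0.46, lin),
            SegmentSpec("FM value", "FM", 6, 0.34, lin)))
        df = add_pps(generate_panel(cfg))
        a4 = TrendModel(df, spec=ModelSpec(basis_dim=4)).fit().aic
        a10 = TrendModel(df, spec=ModelSpec(basis_dim=10)).fit().aic
        assert abs(a4 - a10) <= 0.005 * abs(a10)

    def test_diagnostics_bundle_keys(self):
        df = tiny_panel(n_months=12)
        res = TrendModel(df, spec=ModelSpec(basis_dim=5)).fit(rho=0.3)
        d = res.diagnostics()
        assert {"whitened_lag1_autocorr", "raw_lag1_autocorr",
                "std_resid_quantiles", "rho"} <= set(d)
        assert d["std_resid_quantiles"]["q25"] < d["std_resid_quantiles"]["q75"]


class TestIdentifiability:
    def test_predictions_invariant_to_reference_categories(self):
        df = tiny_panel(n_months=12)
        fit_kw = dict(rho=0.4, lambdas=1.0)
        res1 = TrendModel(df, spec=ModelSpec(basis_dim=5)).fit(**fit_kw)
        res2 = TrendModel(df, spec=ModelSpec(
            basis_dim=5, reference_segment="FM value")).fit(**fit_kw)
        pred1 = res1.predict(df)
        pred2 = res2.predict(df)
        assert np.allclose(pred1, pred2, atol=1e-8)

    def test_fitted_values_decompose_additively(self):
        df = tiny_panel(n_months=12)
        res = TrendModel(df, spec=ModelSpec(basis_dim=5)).fit(rho=0.3,
                                                              lambdas=1.0)
        comp = res.predict_components(month=7, geography="G1",
                                      segment="FM value")
        total = comp["alpha"] + comp["geography"] + comp["segment"] + comp["smooth"]
        assert comp["total"] == pytest.approx(total, abs=1e-12)
        direct = res.predict(month=[7], geography=["G1"], segment=["FM value"])
        assert direct[0] == pytest.approx(comp["total"], abs=1e-12)


class TestDesignShape:
    def test_column_count_fixed_effects_plus_blocks(self):
        df = tiny_panel(n_months=12)
        model = TrendModel(df, spec=ModelSpec(basis_dim=6))
        # 1 intercept + 0 geo dummies (single geography) + 1 segment dummy
        # + two smooth blocks of (6-1) constrained columns
        assert model.exog.shape[1] == 1 + 0 + 1 + 2 * 5

    def test_basis_dim_reduced_when_months_scarce(self, caplog):
        df = tiny_panel(n_months=6)
        with caplog.at_level("WARNING"):
            model = TrendModel(df, spec=ModelSpec(basis_dim=10))
        assert "reducing basis_dim" in caplog.text
        assert model.exog.shape[1] == 1 + 0 + 1 + 2 * 5

    def test_duplicate_months_within_series_rejected(self):
        df = tiny_panel(n_months=6)
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            TrendModel(dup, spec=ModelSpec(basis_dim=4))


class TestResultsApi:
    def test_save_load_round_trip(self, tmp_path):
        df = tiny_panel(n_months=12)
        res = TrendModel(df, spec=ModelSpec(basis_dim=5)).fit(rho=0.3)
        p = tmp_path / "model.json"
        res.save_json(p)
        back = TrendResults.load_json(p)
        assert np.allclose(back.params, res.params)
        assert np.allclose(back.cov, res.cov)
        assert np.allclose(back.predict(df), res.predict(df), atol=1e-10)

    def test_summary_mentions_key_quantities(self):
        df = tiny_panel(n_months=12)
        res = TrendModel(df, spec=ModelSpec(basis_dim=5)).fit(rho=0.3)
        s = res.summary()
        assert "rho" in s and "AIC" in s and "seg[FM value]" in s

    def test_simulated_draws_seeded_and_centred(self):
        df = tiny_panel(n_months=12)
        res = TrendModel(df, spec=ModelSpec(basis_dim=5)).fit(rho=0.3)
        d1 = res.simulate_params(2000, seed=4)
        d2 = res.simulate_params(2000, seed=4)
        assert np.array_equal(d1, d2)
        assert np.allclose(d1.mean(axis=0), res.params,
                           atol=5 * np.max(res.bse) / np.sqrt(2000) * 3 + 1e-6)
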