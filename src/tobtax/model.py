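"""Additive mixed model for per-stick price / net-revenue trends.

The response (real price per stick, or real net revenue per stick) for
observation i at month t, geography j, segment k is modelled as

    y_i = alpha + f_k(t_i) + beta_j + gamma_k + eps_i

with one penalized cubic-regression-spline smooth f_k per market segment,
dummy-coded fixed effects for geography and segment (first level is the
reference), and errors following a stationary AR1 process within each
SKU-by-geography series (correlation rho between consecutive months; a gap
of g months implies correlation rho**g).

Estimation is penalized generalized least squares: the AR1 structure is
removed by exact whitening, smoothing parameters are chosen by a Gaussian
REML criterion (profiled over the log smoothing parameters), and rho by an
outer bounded search minimizing the same criterion, which includes the AR1
log-determinant so values are comparable across rho.  Each smooth is
sum-to-zero centred over its segment's observed months, making the segment
fixed effect gamma_k interpretable as the segment's mean level.

The Results object carries the coefficient vector, the Bayesian posterior
covariance (sigma^2 (X'X + S_lambda)^-1, the basis for simulation-based
confidence intervals downstream), rho, effective degrees of freedom and an
AIC computed from the GLS profile likelihood, so smooth and linear trend
variants are comparable.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .basis import CubicRegressionSpline

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """What to fit: response column, smooth flexibility, grouping, coding."""

    response: str = "pps_real"
    basis_dim: int = 10
    trend: str = "smooth"  # "smooth" or "linear" (per-segment slopes)
    ar1_grouping: str = "sku_geo"  # or "sku"
    reference_geography: str | None = None
    reference_segment: str | None = None
    time_col: str = "month"
    segment_col: str = "segment"
    geography_col: str = "geography"
    sku_col: str = "sku_id"

    def __post_init__(self):
        if self.basis_dim < 4:
            raise ValueError("basis_dim must be >= 4")
        if self.trend not in ("smooth", "linear"):
            raise ValueError("trend must be 'smooth' or 'linear'")
        if self.ar1_grouping not in ("sku_geo", "sku"):
            raise ValueError("ar1_grouping must be 'sku_geo' or 'sku'")


@dataclass
class _SmoothBlock:
    segment: str
    spline: CubicRegressionSpline | None  # None for linear trend
    Z: np.ndarray | None       # constraint null-space, k x (k-1)
    S: np.ndarray | None       # penalty in constrained coords
    rank: int
    sl: slice                  # columns in the full design
    t_center: float            # for linear trend centring


def _ordered_levels(values: pd.Series, reference: str | None) -> list[str]:
    levels = sorted(values.unique().tolist())
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} not present")
        levels.remove(reference)
        levels.insert(0, reference)
    return levels


class TrendDesign:
    """Fixed-effect + smooth design shared between fitting and prediction."""

    def __init__(self, spec: ModelSpec, geo_levels: list[str],
                 seg_levels: list[str], blocks: list[_SmoothBlock],
                 n_columns: int, column_names: list[str]):
        self.spec = spec
        self.geo_levels = geo_levels
        self.seg_levels = seg_levels
        self.blocks = blocks
        self.n_columns = n_columns
        self.column_names = column_names

    @classmethod
    def build(cls, df: pd.DataFrame, spec: ModelSpec) -> "TrendDesign":
        geo_levels = _ordered_levels(df[spec.geography_col], spec.reference_geography)
        seg_levels = _ordered_levels(df[spec.segment_col], spec.reference_segment)
        names = ["intercept"]
        names += [f"geo[{g}]" for g in geo_levels[1:]]
        names += [f"seg[{s}]" for s in seg_levels[1:]]
        col = len(names)
        blocks: list[_SmoothBlock] = []
        for seg in seg_levels:
            t = df.loc[df[spec.segment_col] == seg, spec.time_col].to_numpy(dtype=float)
            uniq = np.unique(t)
            if spec.trend == "linear":
                blocks.append(_SmoothBlock(seg, None, None, None, 0,
                                           slice(col, col + 1), float(uniq.mean())))
                names.append(f"slope[{seg}]")
                col += 1
                continue
            k = spec.basis_dim
            if len(uniq) < k:
                logger.warning("segment %r: only %d distinct months; reducing "
                               "basis_dim from %d", seg, len(uniq), k)
                k = len(uniq)
            if k < 4:
                raise FitError(f"segment {seg!r} has too few distinct months "
                               f"({len(uniq)}) for a smooth")
            knots = np.linspace(uniq.min(), uniq.max(), k)
            spline = CubicRegressionSpline(knots)
            # sum-to-zero over the segment's observed months
            c = spline.design(uniq).sum(axis=0)
            Z = linalg.null_space(c[None, :])
            S_full = spline.penalty()
            S = Z.T @ S_full @ Z
            S = 0.5 * (S + S.T)
            ev = np.linalg.eigvalsh(S)
            rank = int((ev > ev.max() * 1e-9).sum())
            p_k = Z.shape[1]
            blocks.append(_SmoothBlock(seg, spline, Z, S, rank,
                                       slice(col, col + p_k), float(uniq.mean())))
            names += [f"s({seg}).{i}" for i in range(p_k)]
            col += p_k
        return cls(spec, geo_levels, seg_levels, blocks, col, names)

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        spec = self.spec
        n = len(df)
        X = np.zeros((n, self.n_columns))
        X[:, 0] = 1.0
        geo = df[spec.geography_col].to_numpy()
        seg = df[spec.segment_col].to_numpy()
        t = df[spec.time_col].to_numpy(dtype=float)
        unknown_geo = set(np.unique(geo)) - set(self.geo_levels)
        unknown_seg = set(np.unique(seg)) - set(self.seg_levels)
        if unknown_geo or unknown_seg:
            raise FitError(f"levels not seen at fit time: "
                           f"{sorted(unknown_geo) + sorted(unknown_seg)}")
        for idx, g in enumerate(self.geo_levels[1:], start=1):
            X[geo == g, idx] = 1.0
        off = 1 + len(self.geo_levels) - 1
        for idx, s in enumerate(self.seg_levels[1:]):
            X[seg == s, off + idx] = 1.0
        for blk in self.blocks:
            rows = seg == blk.segment
            if not rows.any():
                continue
            if blk.spline is None:
                X[rows, blk.sl.start] = t[rows] - blk.t_center
            else:
                X[np.ix_(rows, range(blk.sl.start, blk.sl.stop))] = (
                    blk.spline.design(t[rows]) @ blk.Z)
        return X

    def penalties(self) -> list[tuple[slice, np.ndarray, int]]:
        return [(b.sl, b.S, b.rank) for b in self.blocks if b.S is not None]

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {"spec": self.spec.__dict__, "geo_levels": self.geo_levels,
             "seg_levels": self.seg_levels, "n_columns": self.n_columns,
             "column_names": self.column_names, "blocks": []}
        for b in self.blocks:
            d["blocks"].append({
                "segment": b.segment,
                "knots": None if b.spline is None else b.spline.knots.tolist(),
                "Z": None if b.Z is None else b.Z.tolist(),
                "rank": b.rank, "start": b.sl.start, "stop": b.sl.stop,
                "t_center": b.t_center,
            })
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrendDesign":
        spec = ModelSpec(**d["spec"])
        blocks = []
        for b in d["blocks"]:
            spline = None if b["knots"] is None else CubicRegressionSpline(b["knots"])
            Z = None if b["Z"] is None else np.asarray(b["Z"])
            S = None
            if spline is not None:
                S = Z.T @ spline.penalty() @ Z
                S = 0.5 * (S + S.T)
            blocks.append(_SmoothBlock(b["segment"], spline, Z, S, b["rank"],
                                       slice(b["start"], b["stop"]), b["t_center"]))
        return cls(spec, d["geo_levels"], d["seg_levels"], blocks,
                   d["n_columns"], d["column_names"])


class TrendModel:
    """Penalized additive model with AR1 errors, statsmodels-style.

    Parameters
    ----------
    data : DataFrame with response, month, geography, segment, sku columns.
    response : response column name (overrides ``spec.response``).
    spec : full ModelSpec; keyword overrides are applied on top.
    """

    def __init__(self, data: pd.DataFrame, response: str | None = None,
                 spec: ModelSpec | None = None, **overrides):
        spec = spec or ModelSpec()
        if response is not None:
            overrides["response"] = response
        if overrides:
            spec = ModelSpec(**{**spec.__dict__, **overrides})
        if spec.response not in data.columns:
            raise ValueError(f"response column {spec.response!r} not in data")
        self.spec = spec
        if spec.ar1_grouping == "sku_geo":
            group_cols = [spec.sku_col, spec.geography_col]
        else:
            group_cols = [spec.sku_col]
        data = data.sort_values(group_cols + [spec.time_col],
                                kind="mergesort").reset_index(drop=True)
        self.data = data
        self.design = TrendDesign.build(data, spec)
        self.exog = self.design.matrix(data)
        self.endog = data[spec.response].to_numpy(dtype=float)
        if np.any(~np.isfinite(self.endog)):
            raise ValueError("response contains non-finite values")
        gid = pd.MultiIndex.from_frame(data[group_cols]).factorize()[0] \
            if len(group_cols) > 1 else data[group_cols[0]].factorize()[0]
        self._first = np.ones(len(data), dtype=bool)
        self._first[1:] = gid[1:] != gid[:-1]
        t = data[spec.time_col].to_numpy(dtype=float)
        gaps = np.zeros(len(data))
        gaps[1:] = t[1:] - t[:-1]
        gaps[self._first] = 0.0
        if np.any(gaps[~self._first] < 1):
            raise ValueError("duplicate or non-increasing months within a "
                             "SKU-by-geography series")
        self._gaps = gaps

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "TrendModel":
        return cls(data, **kw)

    # -- AR1 whitening -------------------------------------------------
    def _whiten(self, rho: float) -> tuple[np.ndarray, np.ndarray, float]:
        X, y = self.exog, self.endog
        if rho == 0.0:
            return X, y, 0.0
        lag = rho ** self._gaps
        denom = np.sqrt(1.0 - lag ** 2)
        nf = ~self._first
        Xw = X.copy()
        yw = y.copy()
        Xw[nf] = (X[nf] - lag[nf, None] * X[np.flatnonzero(nf) - 1]) / denom[nf, None]
        yw[nf] = (y[nf] - lag[nf] * y[np.flatnonzero(nf) - 1]) / denom[nf]
        logdet_corr = float(np.sum(np.log1p(-lag[nf] ** 2)))
        return Xw, yw, logdet_corr

    # -- REML machinery ------------------------------------------------
    def _reml_parts(self, A, b, yy, loglam, penalties, n):
        p = A.shape[0]
        H = A.copy()
        for (sl, S, _), ll in zip(penalties, loglam):
            H[sl, sl] += np.exp(ll) * S
        try:
            cf = linalg.cho_factor(H, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        beta = linalg.cho_solve(cf, b, check_finite=False)
        Dp = yy - b @ beta
        Dp = max(Dp, 1e-300)
        logdet_H = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Mp = p - sum(r for _, _, r in penalties)
        sigma2 = Dp / (n - Mp)
        return beta, Dp, logdet_H, Mp, sigma2, cf

    def _reml_score(self, A, b, yy, loglam, penalties, n, logdet_corr):
        parts = self._reml_parts(A, b, yy, loglam, penalties, n)
        if parts is None:
            return np.inf
        _, _, logdet_H, Mp, sigma2, _ = parts
        score = ((n - Mp) * np.log(sigma2) + logdet_corr + logdet_H
                 - sum(r * ll for (_, _, r), ll in zip(penalties, loglam)))
        return float(score)

    def _profile_lambda(self, A, b, yy, n, logdet_corr, loglam0):
        penalties = self.design.penalties()
        if not penalties:
            score = self._reml_score(A, b, yy, [], penalties, n, logdet_corr)
            return np.array([]), score
        fun = lambda ll: self._reml_score(A, b, yy, ll, penalties, n, logdet_corr)
        res = optimize.minimize(fun, np.asarray(loglam0, dtype=float),
                                method="L-BFGS-B",
                                bounds=[(-10.0, 18.0)] * len(penalties),
                                options={"maxiter": 200, "ftol": 1e-10})
        return res.x, float(res.fun)

    def fit(self, rho: float | None = None,
            lambdas: float | Sequence[float] | None = None,
            rho_bounds: tuple[float, float] = (-0.5, 0.995),
            rho_tol: float = 1.5e-3) -> "TrendResults":
        """Fit by penalized GLS.

        rho : fix the AR1 coefficient, or None to estimate it by profiling
            the REML criterion.
        lambdas : fix the smoothing parameters (scalar or one per segment;
            0 means unpenalized), or None to estimate them by REML.
        """
        penalties = self.design.penalties()
        n = len(self.endog)
        K = len(penalties)

        fixed_lam = None
        if lambdas is not None:
            fixed_lam = np.full(K, float(lambdas)) if np.isscalar(lambdas) \
                else np.asarray(lambdas, dtype=float)
            if len(fixed_lam) != K:
                raise ValueError(f"expected {K} smoothing parameters")

        state = {"loglam": np.zeros(K)}

        def at_rho(r):
            Xw, yw, logdet_corr = self._whiten(r)
            A = Xw.T @ Xw
            b = Xw.T @ yw
            yy = float(yw @ yw)
            if fixed_lam is not None:
                if np.all(fixed_lam == 0.0) or K == 0:
                    # unpenalized: plain least squares on whitened data
                    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
                    resid = yw - Xw @ beta
                    rss = float(resid @ resid)
                    p = A.shape[0]
                    sigma2 = rss / max(n - p, 1)
                    score = ((n - p) * np.log(max(sigma2, 1e-300)) + logdet_corr
                             + np.linalg.slogdet(A)[1])
                    return score, beta, np.zeros(K), A, b, yy, logdet_corr
                loglam = np.log(fixed_lam)
                score = self._reml_score(A, b, yy, loglam, penalties, n, logdet_corr)
                parts = self._reml_parts(A, b, yy, loglam, penalties, n)
                if parts is None:
                    raise FitError("penalized system not positive definite")
                return score, parts[0], loglam, A, b, yy, logdet_corr
            loglam, score = self._profile_lambda(A, b, yy, n, logdet_corr,
                                                 state["loglam"])
            state["loglam"] = loglam.copy() if K else np.zeros(0)
            return score, None, loglam, A, b, yy, logdet_corr

        if rho is not None:
            if not (-1.0 < rho < 1.0):
                raise ValueError("rho must satisfy |rho| < 1")
            rho_hat = float(rho)
            rho_estimated = False
        else:
            res = optimize.minimize_scalar(
                lambda r: at_rho(r)[0], bounds=rho_bounds, method="bounded",
                options={"xatol": rho_tol, "maxiter": 60})
            if not res.success:
                raise FitError(f"rho search failed: {res.message}")
            rho_hat = float(res.x)
            rho_estimated = True

        score, beta, loglam, A, b, yy, logdet_corr = at_rho(rho_hat)
        lam = np.exp(loglam) if K else np.zeros(0)
        if fixed_lam is not None:
            lam = fixed_lam

        # final quantities at (rho_hat, lam)
        Xw, yw, logdet_corr = self._whiten(rho_hat)
        p = self.design.n_columns
        H = Xw.T @ Xw
        A = H.copy()
        for (sl, S, _), l in zip(penalties, lam):
            if l > 0:
                H[sl, sl] += l * S
        if beta is None or fixed_lam is None:
            try:
                cf = linalg.cho_factor(H, lower=True, check_finite=False)
                beta = linalg.cho_solve(cf, Xw.T @ yw, check_finite=False)
            except linalg.LinAlgError:
                beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid_w = yw - Xw @ beta
        rss_w = float(resid_w @ resid_w)
        if lam.size and np.any(lam > 0):
            Mp = p - sum(r for _, _, r in penalties)
        else:
            Mp = p
        Dp = rss_w + sum(float(l * beta[sl] @ S @ beta[sl])
                         for (sl, S, _), l in zip(penalties, lam))
        sigma2_reml = Dp / max(n - Mp, 1)
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            Hinv = np.linalg.pinv(H)
        edf = float(np.trace(Hinv @ A))
        cov = sigma2_reml * Hinv
        cov = 0.5 * (cov + cov.T)
        sigma2_ml = rss_w / n
        loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet_corr + n)
        k_extra = 1 + (1 if rho_estimated else 0)  # sigma, rho
        aic = -2.0 * loglik + 2.0 * (edf + k_extra)

        return TrendResults(
            model=self, design=self.design, params=np.asarray(beta),
            cov=cov, rho=rho_hat, rho_estimated=rho_estimated,
            lambdas=lam, sigma2=sigma2_reml, sigma2_ml=sigma2_ml,
            edf=edf, aic=float(aic), loglik=float(loglik), score=float(score),
            n_obs=n, resid_whitened=resid_w,
            fittedvalues=self.exog @ beta)


@dataclass
class TrendResults:
    """Fitted additive AR1 model: estimates, uncertainty, diagnostics."""

    model: TrendModel | None
    design: TrendDesign
    params: np.ndarray
    cov: np.ndarray
    rho: float
    rho_estimated: bool
    lambdas: np.ndarray
    sigma2: float          # REML-scale marginal error variance
    sigma2_ml: float
    edf: float
    aic: float
    loglik: float
    score: float
    n_obs: int
    resid_whitened: np.ndarray | None = None
    fittedvalues: np.ndarray | None = None

    @property
    def param_names(self) -> list[str]:
        return self.design.column_names

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def cov_params(self) -> np.ndarray:
        return self.cov

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.param_names)

    # -- prediction ----------------------------------------------------
    def predict(self, data: pd.DataFrame | None = None, *, month=None,
                geography=None, segment=None) -> np.ndarray:
        """Fitted response for records or for explicit (month, geo, segment)."""
        if data is None:
            data = pd.DataFrame({
                self.design.spec.time_col: np.atleast_1d(month),
                self.design.spec.geography_col: geography,
                self.design.spec.segment_col: segment,
            })
        return self.design.matrix(data) @ self.params

    def predict_components(self, month, geography, segment) -> dict[str, float]:
        """Additive decomposition alpha + beta_j + gamma_k + f_k(t)."""
        d = self.design
        row = d.matrix(pd.DataFrame({
            d.spec.time_col: [month], d.spec.geography_col: [geography],
            d.spec.segment_col: [segment]}))[0]
        comp = {"alpha": self.params[0]}
        ng = len(d.geo_levels) - 1
        comp["geography"] = float(row[1:1 + ng] @ self.params[1:1 + ng])
        ns = len(d.seg_levels) - 1
        comp["segment"] = float(row[1 + ng:1 + ng + ns]
                                @ self.params[1 + ng:1 + ng + ns])
        smooth = 0.0
        for blk in d.blocks:
            if blk.segment == segment:
                smooth = float(row[blk.sl] @ self.params[blk.sl])
        comp["smooth"] = smooth
        comp["total"] = float(row @ self.params)
        return comp

    # -- simulation ----------------------------------------------------
    def simulate_params(self, n_draws: int, seed=None) -> np.ndarray:
        """Draws from N(params, cov): the posterior-simulation basis for CIs."""
        cov = self.cov
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            # semi-definite repair: eigen square root, tolerating negative
            # eigenvalues only up to a 1e-10 jitter bound
            w, V = np.linalg.eigh(cov)
            if w.min() < -1e-10 * max(1.0, w.max()):
                raise FitError("coefficient covariance is not positive "
                               "semi-definite (beyond the 1e-10 jitter bound)")
            L = V * np.sqrt(np.clip(w, 0.0, None))
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((int(n_draws), len(self.params)))
        return self.params[None, :] + z @ L.T

    # -- diagnostics ---------------------------------------------------
    def whitened_lag1_autocorr(self) -> float:
        """Pooled lag-1 autocorrelation of AR1-whitened residuals.

        Near zero when the AR1 assumption matches the data.
        """
        if self.model is None or self.resid_whitened is None:
            raise FitError("diagnostics need the fitting data")
        r = self.resid_whitened
        nf = ~self.model._first
        prev = np.flatnonzero(nf) - 1
        num = float(r[nf] @ r[prev])
        den = float(r @ r)
        return num / den if den > 0 else 0.0

    def raw_lag1_autocorr(self) -> float:
        """Same statistic on unwhitened residuals (shows the AR1 if ignored)."""
        if self.model is None or self.fittedvalues is None:
            raise FitError("diagnostics need the fitting data")
        r = self.model.endog - self.fittedvalues
        nf = ~self.model._first
        prev = np.flatnonzero(nf) - 1
        den = float(r @ r)
        return float(r[nf] @ r[prev]) / den if den > 0 else 0.0

    def diagnostics(self) -> dict:
        r = self.resid_whitened / np.sqrt(self.sigma2)
        qq = np.quantile(r, [0.01, 0.25, 0.5, 0.75, 0.99])
        return {
            "whitened_lag1_autocorr": self.whitened_lag1_autocorr(),
            "raw_lag1_autocorr": self.raw_lag1_autocorr(),
            "std_resid_quantiles": dict(zip(["q01", "q25", "q50", "q75", "q99"],
                                            qq.tolist())),
            "rho": self.rho, "sigma2": self.sigma2, "edf": self.edf,
        }

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        lines = []
        d = self.design
        lines.append("Additive AR1 trend model")
        lines.append(f"  response: {d.spec.response}   trend: {d.spec.trend}")
        lines.append(f"  n_obs: {self.n_obs}   edf: {self.edf:.2f}   "
                     f"AIC: {self.aic:.1f}")
        lines.append(f"  rho: {self.rho:.4f}"
                     + (" (estimated)" if self.rho_estimated else " (fixed)")
                     + f"   sigma: {np.sqrt(self.sigma2):.5f} GBP/stick")
        lines.append("")
        lines.append(f"  {'term':<28}{'estimate':>12}{'std err':>12}")
        se = self.bse
        n_fixed = 1 + (len(d.geo_levels) - 1) + (len(d.seg_levels) - 1)
        for i in range(n_fixed):
            lines.append(f"  {self.param_names[i]:<28}{self.params[i]:>12.5f}"
                         f"{se[i]:>12.5f}")
        if d.spec.trend == "smooth":
            lines.append("")
            lines.append(f"  {'smooth':<28}{'edf':>8}{'lambda':>12}")
            lams = self.lambdas if len(self.lambdas) else [0.0] * len(d.blocks)
            for blk, lam in zip(d.blocks, lams):
                name = f"s({blk.segment})"
                lines.append(f"  {name:<28}{self._block_edf(blk):>8.2f}"
                             f"{lam:>12.3g}")
        return "\n".join(lines)

    def _block_edf(self, blk) -> float:
        # per-smooth edf from the covariance ratio tr(Vp A)/sigma2 restricted
        # to the block; falls back to column count if data unavailable
        if self.model is None:
            return float(blk.sl.stop - blk.sl.start)
        Xw, _, _ = self.model._whiten(self.rho)
        Xb = Xw[:, blk.sl]
        Vb = self.cov[blk.sl, blk.sl] / self.sigma2
        return float(np.trace(Vb @ (Xb.T @ Xb)))

    # -- persistence ---------------------------------------------------
    def save_json(self, path) -> None:
        doc = {
            "design": self.design.to_dict(),
            "params": self.params.tolist(),
            "cov": self.cov.tolist(),
            "rho": self.rho, "rho_estimated": self.rho_estimated,
            "lambdas": np.asarray(self.lambdas).tolist(),
            "sigma2": self.sigma2, "sigma2_ml": self.sigma2_ml,
            "edf": self.edf, "aic": self.aic, "loglik": self.loglik,
            "score": self.score, "n_obs": self.n_obs,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load_json(cls, path) -> "TrendResults":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(model=None, design=TrendDesign.from_dict(doc["design"]),
                   params=np.asarray(doc["params"]), cov=np.asarray(doc["cov"]),
                   rho=doc["rho"], rho_estimated=doc["rho_estimated"],
                   lambdas=np.asarray(doc["lambdas"]), sigma2=doc["sigma2"],
                   sigma2_ml=doc["sigma2_ml"], edf=doc["edf"], aic=doc["aic"],
                   loglik=doc["loglik"], score=doc["score"],
                   n_obs=doc["n_obs"])


def compare_linear_vs_smooth(data: pd.DataFrame, response: str = "pps_real",
                             spec: ModelSpec | None = None,
                             rho: float | None = None) -> tuple[float, float, str]:
    """AIC of the per-segment-slope linear model vs the smooth model.

    Both are fitted with the same AR1 machinery and the same likelihood
    definition, so the AICs are directly comparable; lower wins.
    """
    spec = spec or ModelSpec()
    base = {**spec.__dict__, "response": response}
    lin = TrendModel(data, spec=ModelSpec(**{**base, "trend": "linear"})).fit(rho=rho)
    smo = TrendModel(data, spec=ModelSpec(**{**base, "trend": "smooth"})).fit(rho=rho)
    preferred = "smooth" if smo.aic < lin.aic else "linear"
    return lin.aic, smo.aic, preferred
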