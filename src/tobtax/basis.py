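"""Cubic regression spline basis with curvature penalty.

A natural cubic spline is parameterised by its values at k knots; the basis
functions are the cardinal splines (the j-th basis function interpolates 1 at
knot j and 0 at the others).  The wiggliness penalty is the exact integrated
squared second derivative, a rank k-2 quadratic form whose null space is the
constant and linear functions.

Construction (banded matrices over knot spacings h_j = x_{j+1} - x_j):

    D (k-2 x k):  D[i,i] = 1/h_i,  D[i,i+1] = -1/h_i - 1/h_{i+1},
                  D[i,i+2] = 1/h_{i+1}
    B (k-2 x k-2, sym. tridiag.):  B[i,i] = (h_i + h_{i+1})/3,
                  B[i,i+1] = h_{i+1}/6

Second derivatives at the interior knots are then B^{-1} D beta and the
penalty matrix is S = D' B^{-1} D.  Evaluation between knots uses the usual
piecewise-cubic form; outside the knot range the spline continues linearly
(the natural boundary condition).
"""
from __future__ import annotations

import numpy as np


class CubicRegressionSpline:
    """Cardinal natural cubic spline basis on a fixed knot sequence."""

    def __init__(self, knots):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or len(knots) < 3:
            raise ValueError("need at least 3 strictly increasing knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        k = len(knots)
        h = np.diff(knots)
        D = np.zeros((k - 2, k))
        B = np.zeros((k - 2, k - 2))
        for i in range(k - 2):
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < k - 2:
                B[i, i + 1] = h[i + 1] / 6.0
                B[i + 1, i] = h[i + 1] / 6.0
        self._h = h
        self._D = D
        self._B = B
        # F maps knot values to second derivatives at all knots (natural
        # boundary: zero curvature at the end knots).
        F = np.zeros((k, k))
        F[1:-1, :] = np.linalg.solve(B, D)
        self._F = F

    @property
    def n_basis(self) -> int:
        return len(self.knots)

    def penalty(self) -> np.ndarray:
        """Integrated squared second derivative, S = D' B^{-1} D."""
        return self._D.T @ np.linalg.solve(self._B, self._D)

    def _piece(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        j = np.searchsorted(self.knots, x, side="right") - 1
        j = np.clip(j, 0, len(self.knots) - 2)
        return j, x

    def design(self, x) -> np.ndarray:
        """Basis matrix; row i evaluates all k basis functions at x[i]."""
        x = np.asarray(x, dtype=float)
        flat = np.ravel(x)
        k = len(self.knots)
        lo, hi = self.knots[0], self.knots[-1]
        inside = np.clip(flat, lo, hi)
        j, _ = self._piece(inside)
        h = self._h[j]
        xr = self.knots[j + 1] - inside
        xl = inside - self.knots[j]
        out = np.zeros((len(flat), k))
        rows = np.arange(len(flat))
        # value part
        out[rows, j] += xr / h
        out[rows, j + 1] += xl / h
        # curvature part via F
        cm = (xr ** 3 / h - h * xr) / 6.0
        cp = (xl ** 3 / h - h * xl) / 6.0
        out += cm[:, None] * self._F[j] + cp[:, None] * self._F[j + 1]
        # linear extrapolation beyond the knot range
        outside = (flat < lo) | (flat > hi)
        if np.any(outside):
            bx = np.where(flat < lo, lo, hi)[outside]
            slope = self._derivative_rows(bx)
            out[outside] += (flat[outside] - bx)[:, None] * slope
        return out.reshape(x.shape + (k,)) if x.ndim > 1 else out

    def _derivative_rows(self, x: np.ndarray) -> np.ndarray:
        """Rows mapping knot values to f'(x), for x inside the knot range."""
        x = np.asarray(x, dtype=float)
        j, _ = self._piece(np.clip(x, self.knots[0], self.knots[-1]))
        h = self._h[j]
        xr = self.knots[j + 1] - x
        xl = x - self.knots[j]
        out = np.zeros((len(x), len(self.knots)))
        rows = np.arange(len(x))
        out[rows, j] += -1.0 / h
        out[rows, j + 1] += 1.0 / h
        dcm = (-3.0 * xr ** 2 / h + h) / 6.0
        dcp = (3.0 * xl ** 2 / h - h) / 6.0
        out += dcm[:, None] * self._F[j] + dcp[:, None] * self._F[j + 1]
        return out
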