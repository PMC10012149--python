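"""Maximum-likelihood linear mixed model with a single random intercept.

The permutation screen refits the same random-intercept model tens of
thousands of times (features x permutations), so the fitter exploits the
model's structure instead of generic mixed-model machinery. For

    y = X beta + Z b + e,   b ~ N(0, sigma_b^2 I),  e ~ N(0, sigma^2 I)

with one grouping factor (participant), the marginal covariance is
``sigma^2 (I + theta Z Z')`` with ``theta = sigma_b^2 / sigma^2``. Both beta
and sigma^2 profile out in closed form, leaving a 1-D likelihood in theta.
Writing per-group column sums ``s_g = X_g' 1`` and ``t_g = 1' y_g``:

    Xt'Xt = X'X - sum_g w_g s_g s_g',   w_g = theta / (1 + theta n_g)
    Xt'yt = X'y - sum_g w_g s_g t_g,    yt'yt = y'y - sum_g w_g t_g^2
    log|I + theta ZZ'| = sum_g log(1 + theta n_g)

so each likelihood evaluation costs O(G p^2) regardless of n, and the
per-feature cross-products are shared across every theta evaluation. The
resulting maximized log-likelihood is exact ML (validated against an
independent general-purpose mixed-model implementation in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

__all__ = ["RandomInterceptModel", "YStats"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class YStats:
    """Per-response sufficient statistics (supports F responses at once)."""

    XtY: np.ndarray  # (p, F)
    T: np.ndarray    # (G, F) per-group response sums
    yty: np.ndarray  # (F,)
    var: np.ndarray  # (F,) response variances, used for degeneracy floors


class RandomInterceptModel:
    """Profiled-ML fitter for a fixed design ``X`` and grouping vector."""

    def __init__(self, X: np.ndarray, groups: np.ndarray):
        X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        if X.ndim != 2 or len(groups) != X.shape[0]:
            raise ValueError("X must be (n, p) with one group code per row")
        codes, counts = np.unique(groups, return_counts=True)
        code_index = {c: i for i, c in enumerate(codes)}
        g = np.array([code_index[c] for c in groups])
        self.n, self.p = X.shape
        self.G = len(codes)
        self.ng = counts.astype(float)
        self.X = X
        self.g = g
        self.XtX = X.T @ X
        S = np.zeros((self.G, self.p))
        np.add.at(S, g, X)
        self.S = S

    def prepare_y(self, Y: np.ndarray) -> YStats:
        """Cross-products for one response vector or an (n, F) matrix."""
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        XtY = self.X.T @ Y
        T = np.zeros((self.G, Y.shape[1]))
        np.add.at(T, self.g, Y)
        yty = (Y * Y).sum(axis=0)
        return YStats(XtY=XtY, T=T, yty=yty, var=Y.var(axis=0))

    # -- profile likelihood ------------------------------------------------
    def _loglik_at(self, theta: float, stats: YStats, f: int) -> float:
        w = theta / (1.0 + theta * self.ng)
        A = self.XtX - (self.S.T * w) @ self.S
        b = stats.XtY[:, f] - self.S.T @ (w * stats.T[:, f])
        c = stats.yty[f] - float(w @ (stats.T[:, f] ** 2))
        try:
            cf = linalg.cho_factor(A, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise ValueError("singular fixed-effect design (e.g. a single meal)") from exc
        beta = linalg.cho_solve(cf, b, check_finite=False)
        rss = c - float(b @ beta)
        # floor guards exact-fit degeneracies (e.g. zero-noise simulations)
        floor = self.n * max(stats.var[f], 1e-300) * 1e-12
        rss = max(rss, floor, 1e-300)
        logdet = float(np.log1p(theta * self.ng).sum())
        return -0.5 * (self.n * (_LOG_2PI + np.log(rss / self.n) + 1.0) + logdet)

    def max_loglik(self, stats: YStats, f: int = 0) -> float:
        """Maximized ML log-likelihood over theta in [0, inf)."""
        obj = lambda x: -self._loglik_at(np.exp(x), stats, f)
        res = optimize.minimize_scalar(
            obj, bounds=(-10.0, 8.0), method="bounded", options={"xatol": 2e-3}
        )
        best = -res.fun
        at_zero = self._loglik_at(0.0, stats, f)
        return max(best, at_zero)

    def fit_feature(self, y: np.ndarray) -> float:
        """Convenience: maximized log-likelihood for a single response."""
        return self.max_loglik(self.prepare_y(y), 0)
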