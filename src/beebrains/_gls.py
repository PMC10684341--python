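"""Generalized least squares under a lambda-scaled phylogenetic covariance.

Shared machinery for the allometric PGLS fit and the phylogenetic-signal
estimator: the multivariate-normal log-likelihood with covariance
``sigma2 * V(lam)`` is profiled over the regression coefficients and the
residual rate, leaving a one-dimensional likelihood in Pagel's lambda that is
maximized on [0, 1].
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar


class SingularDesignError(ValueError):
    """Raised when the regression design is rank-deficient."""


def lambda_cov(V: np.ndarray, lam: float) -> np.ndarray:
    """``V(lam)``: off-diagonals scaled by lam, diagonal untouched."""
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    return out


def gls_ml(y: np.ndarray, X: np.ndarray, V: np.ndarray, lam: float):
    """ML generalized least squares at a fixed lambda.

    Returns ``(beta, sigma2, loglik, whitened_residuals)`` where the
    whitened residuals are ``L^{-1}(y - X beta)`` for ``V(lam) = L L'``.
    """
    n = len(y)
    Vl = lambda_cov(V, lam)
    try:
        L = np.linalg.cholesky(Vl)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.mean(np.diag(Vl))
        L = np.linalg.cholesky(Vl + jitter * np.eye(n))
    yt = solve_triangular(L, y, lower=True)
    Xt = solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    if rank < X.shape[1]:
        raise SingularDesignError(
            "design matrix is rank-deficient (constant predictor?)"
        )
    resid = y - X @ beta
    et = solve_triangular(L, resid, lower=True)
    sigma2 = float(et @ et) / n
    sigma2 = max(sigma2, 1e-300)
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return beta, sigma2, float(loglik), et


class LambdaProfiler:
    """Profile log-likelihood in lambda, with an ultrametric fast path.

    When the diagonal of ``V`` is constant (ultrametric tree), ``V(lam)``
    shares the eigenvectors of ``V`` for every lambda, so one
    eigendecomposition turns each profile evaluation into an O(n p) solve;
    the decomposition can be reused across responses on the same tree via
    :meth:`with_response` (the parametric bootstrap relies on this).
    Non-constant diagonals fall back to a Cholesky factorization per
    evaluation.
    """

    def __init__(self, y, X, V, decomp=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.V = V
        d = np.diag(V)
        self.d0 = float(d[0])
        self.fast = bool(np.ptp(d) <= 1e-10 * max(1.0, abs(self.d0)))
        if self.fast:
            if decomp is None:
                w, Q = np.linalg.eigh(V)
                decomp = (w, Q)
            self.w, self.Q = decomp
            self.yr = self.Q.T @ self.y
            self.Xr = self.Q.T @ self.X
        else:
            self.w = self.Q = None

    def with_response(self, y) -> "LambdaProfiler":
        decomp = (self.w, self.Q) if self.fast else None
        return LambdaProfiler(y, self.X, self.V, decomp=decomp)

    def loglik(self, lam: float) -> float:
        if not self.fast:
            return gls_ml(self.y, self.X, self.V, lam)[2]
        n = len(self.y)
        d = np.clip(lam * self.w + (1.0 - lam) * self.d0, 1e-12, None)
        s = 1.0 / np.sqrt(d)
        yt = self.yr * s
        Xt = self.Xr * s[:, None]
        beta, _, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
        if rank < self.X.shape[1]:
            raise SingularDesignError(
                "design matrix is rank-deficient (constant predictor?)"
            )
        e = yt - Xt @ beta
        sigma2 = max(float(e @ e) / n, 1e-300)
        logdet = float(np.log(d).sum())
        return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)

    def profile(self, *, n_grid: int = 51, xatol: float = 1e-10) -> tuple[float, float]:
        """Maximize the profile log-likelihood over lambda in [0, 1].

        A coarse grid locates the basin; a bounded Brent refinement
        polishes the optimum.  The returned lambda is the best of grid
        points, refinement and the two endpoints, so the profile value at
        the estimate is never below the grid maximum.
        """
        grid = np.linspace(0.0, 1.0, n_grid)
        grid_ll = np.array([self.loglik(g) for g in grid])
        k = int(np.argmax(grid_ll))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, n_grid - 1)]
        candidates = [
            (grid[k], grid_ll[k]),
            (0.0, grid_ll[0]),
            (1.0, grid_ll[-1]),
        ]
        if hi > lo:
            res = minimize_scalar(
                lambda lam: -self.loglik(lam),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": xatol},
            )
            candidates.append((float(res.x), -float(res.fun)))
        lam_hat, ll_hat = max(candidates, key=lambda t: t[1])
        return float(lam_hat), float(ll_hat)


def profile_lambda(
    y: np.ndarray,
    X: np.ndarray,
    V: np.ndarray,
    *,
    n_grid: int = 51,
    xatol: float = 1e-10,
) -> tuple[float, float]:
    """Convenience wrapper: build a :class:`LambdaProfiler` and profile."""
    return LambdaProfiler(y, X, V).profile(n_grid=n_grid, xatol=xatol)
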