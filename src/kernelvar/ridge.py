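"""Bayesian ridge regression with evidence-optimized hyperparameters.

The model is ``y = Xw + eps`` with ``w ~ N(0, sigma_p^2 I)`` and
``eps ~ N(0, sigma_n^2 I)``.  The two variances are found by maximizing the
Gaussian marginal likelihood ``N(y; 0, sigma_n^2 I + sigma_p^2 X X^T)``; the
posterior mean then equals the ridge solution at ``lam = sigma_n^2 /
sigma_p^2``.  The ratio ``SNR = sigma_p^2 / sigma_n^2`` summarizes the
relative magnitude of signal and noise; its inverse tracks response
variability across animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.sparse

__all__ = [
    "RidgeHyperparams",
    "ridge_solve",
    "ridge_evidence",
    "compute_snr",
    "marginal_log_likelihood",
]

#: Bounds on both variances, in units of the (normalized) response.
VAR_BOUNDS = (1e-8, 1e4)


@dataclass
class RidgeHyperparams:
    """Prior variance, noise variance, and their ratio."""

    sigma_p2: float
    sigma_n2: float

    def __post_init__(self) -> None:
        if self.sigma_p2 <= 0 or self.sigma_n2 <= 0:
            raise ValueError("variances must be positive")

    @property
    def snr(self) -> float:
        return self.sigma_p2 / self.sigma_n2


def compute_snr(h: RidgeHyperparams) -> float:
    """Signal-to-noise ratio sigma_p^2 / sigma_n^2."""
    return h.snr


def _dense(X) -> np.ndarray:
    if scipy.sparse.issparse(X):
        return np.asarray(X.todense())
    values = getattr(X, "values", X)
    if scipy.sparse.issparse(values):
        values = np.asarray(values.todense())
    return np.asarray(values, dtype=float)


def ridge_solve(X, y: np.ndarray, lam: float) -> np.ndarray:
    """Ridge estimate ``(X^T X + lam I)^{-1} X^T y`` (lam = 0 gives OLS)."""
    Xv = _dense(X)
    d = Xv.shape[1]
    return np.linalg.solve(Xv.T @ Xv + lam * np.eye(d), Xv.T @ y)


@dataclass
class _SVDCache:
    """Sufficient statistics for fast evidence evaluations."""

    lam: np.ndarray      # squared singular values (k = min(n, d))
    c2: np.ndarray       # squared projections of y on left singular vectors
    yty: float
    n: int
    V: np.ndarray        # right singular vectors (d x k)
    Uty: np.ndarray      # projections of y (k,)
    s: np.ndarray        # singular values


def _svd_cache(X: np.ndarray, y: np.ndarray) -> _SVDCache:
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    Uty = U.T @ y
    return _SVDCache(lam=s**2, c2=Uty**2, yty=float(y @ y), n=len(y),
                     V=Vt.T, Uty=Uty, s=s)


def marginal_log_likelihood(X, y: np.ndarray, sigma_p2: float,
                            sigma_n2: float) -> float:
    """log N(y; 0, sigma_n^2 I + sigma_p^2 X X^T), computed stably via SVD."""
    cache = _svd_cache(_dense(X), np.asarray(y, dtype=float))
    return _evidence_from_cache(cache, sigma_p2, sigma_n2)


def _evidence_from_cache(c: _SVDCache, sigma_p2: float, sigma_n2: float) -> float:
    ev = sigma_n2 + sigma_p2 * c.lam
    logdet = float(np.sum(np.log(ev))) + (c.n - c.lam.size) * np.log(sigma_n2)
    quad = (c.yty - float(np.sum(c.c2 * sigma_p2 * c.lam / ev))) / sigma_n2
    return -0.5 * (c.n * np.log(2.0 * np.pi) + logdet + quad)


def ridge_evidence(X, y: np.ndarray, n_restarts: int = 5,
                   tol: float = 1e-8) -> tuple[RidgeHyperparams, np.ndarray, dict]:
    """Evidence-optimized ridge: hyperparameters, posterior-mean weights, info.

    Optimizes ``(log sigma_p^2, log sigma_n^2)`` with bounded L-BFGS-B from
    several log-spaced starting points.  ``info`` reports convergence status,
    the attained log evidence, and whether a variance bound was hit.
    """
    Xv = _dense(X)
    y = np.asarray(y, dtype=float)
    cache = _svd_cache(Xv, y)
    log_bounds = (np.log(VAR_BOUNDS[0]), np.log(VAR_BOUNDS[1]))

    def neg(logs: np.ndarray) -> float:
        return -_evidence_from_cache(cache, np.exp(logs[0]), np.exp(logs[1]))

    var_y = max(cache.yty / max(cache.n, 1), VAR_BOUNDS[0] * 10)
    starts = []
    for f in np.logspace(-2, 2, n_restarts):
        starts.append(np.log([var_y * f, var_y / f]))

    best = None
    for x0 in starts:
        res = scipy.optimize.minimize(
            neg, x0, method="L-BFGS-B",
            bounds=[log_bounds, log_bounds],
            options={"ftol": tol, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res

    sigma_p2, sigma_n2 = np.exp(best.x)
    hyper = RidgeHyperparams(sigma_p2=float(sigma_p2), sigma_n2=float(sigma_n2))
    lam = sigma_n2 / sigma_p2
    # posterior mean from the same SVD: V diag(s / (lam + s^2)) U^T y
    w = cache.V @ (cache.s / (cache.lam + lam) * cache.Uty)
    at_bound = bool(
        np.any(np.isclose(best.x, log_bounds[0], atol=1e-6))
        or np.any(np.isclose(best.x, log_bounds[1], atol=1e-6))
    )
    info = {
        "converged": bool(best.success),
        "log_evidence": float(-best.fun),
        "at_bound": at_bound,
        "n_iter": int(best.nit),
    }
    return hyper, w, info
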