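"""Shared REML machinery for one-random-effect Gaussian models.

Model: y = X b + u + e with u ~ N(0, sigma_g^2 K) and e ~ N(0, sigma_e^2 I).
Writing delta = sigma_e^2 / sigma_g^2 and eigendecomposing K = U D U', the
rotated data y~ = U'y have diagonal covariance sigma_g^2 (D + delta I), so
the restricted likelihood profiles analytically over b and sigma_g^2 and is
maximized over the single scalar delta (log-scale grid bracketing followed
by Brent refinement).

The REML log-likelihood convention used throughout (and reproduced by the
dense-matrix oracle in the test suite) is

    l_R = -1/2 [ (n-q) ln 2pi + ln|V| + ln|X' V^-1 X| + y' P y ]

with V = sigma_g^2 K + sigma_e^2 I and P the REML projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["EigenK", "RemlResult", "eigen_k", "reml_loglik_profiled", "fit_reml"]


@dataclass
class EigenK:
    d: np.ndarray  # eigenvalues, ascending, clipped at 0
    U: np.ndarray  # eigenvectors (columns)


def eigen_k(K: np.ndarray, tol: float = 1e-8) -> EigenK:
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("K must be symmetric")
    d, U = np.linalg.eigh(K)
    if d.min() < -tol:
        raise ValueError(f"K is not positive semi-definite (min eigenvalue {d.min():.3g})")
    return EigenK(np.clip(d, 0.0, None), U)


@dataclass
class RemlResult:
    delta: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    beta: np.ndarray
    eigen: EigenK


def _profile(delta: float, yt: np.ndarray, Xt: np.ndarray, d: np.ndarray):
    """Profiled REML pieces at a given delta on rotated data."""
    n, q = Xt.shape
    w = 1.0 / (d + delta)
    Xw = Xt * w[:, None]
    A = Xt.T @ Xw
    b = Xw.T @ yt
    beta = np.linalg.solve(A, b)
    rss = float(w @ (yt - Xt @ beta) ** 2)
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'WX not positive definite (rank-deficient X?)")
    sum_log = float(np.log(d + delta).sum())
    return rss, logdet_a, sum_log, beta


def reml_loglik_profiled(delta: float, yt: np.ndarray, Xt: np.ndarray, d: np.ndarray) -> float:
    """REML log-likelihood at delta with sigma_g^2 profiled out."""
    n, q = Xt.shape
    nq = n - q
    rss, logdet_a, sum_log, _ = _profile(delta, yt, Xt, d)
    sigma_g2 = rss / nq
    return -0.5 * (
        nq * math.log(2.0 * math.pi)
        + nq * math.log(sigma_g2)
        + sum_log
        + logdet_a
        + nq
    )


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | None = None,
    eigen: EigenK | None = None,
    bounds: tuple[float, float] = (1e-5, 1e5),
    n_grid: int = 100,
) -> RemlResult:
    """Maximize the restricted likelihood over delta = sigma_e^2 / sigma_g^2.

    A ``n_grid``-point log-scale grid over ``bounds`` brackets the optimum,
    then Brent refines within the bracketing interval.  Grid endpoints are
    honored as boundary solutions (e.g. delta at the upper bound when the
    polygenic variance is effectively zero).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("y and X lengths disagree")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix X is rank-deficient")
    if eigen is None:
        if K is None:
            raise ValueError("provide K or its eigendecomposition")
        eigen = eigen_k(K)
    d, U = eigen.d, eigen.U
    yt = U.T @ y
    Xt = U.T @ X

    lo, hi = math.log10(bounds[0]), math.log10(bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([reml_loglik_profiled(10.0**g, yt, Xt, d) for g in grid])
    k = int(np.argmax(vals))
    if 0 < k < n_grid - 1:
        res = optimize.minimize_scalar(
            lambda lg: -reml_loglik_profiled(10.0**lg, yt, Xt, d),
            bracket=None,
            bounds=(grid[k - 1], grid[k + 1]),
            method="bounded",
            options={"xatol": 1e-8},
        )
        log_delta = float(res.x)
        if -res.fun < vals[k]:
            log_delta = float(grid[k])
    else:
        log_delta = float(grid[k])
    delta = 10.0**log_delta
    rss, _, _, beta = _profile(delta, yt, Xt, d)
    nq = y.size - X.shape[1]
    sigma_g2 = rss / nq
    return RemlResult(
        delta=delta,
        sigma_g2=sigma_g2,
        sigma_e2=delta * sigma_g2,
        loglik=reml_loglik_profiled(delta, yt, Xt, d),
        beta=beta,
        eigen=eigen,
    )
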