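"""Exact single-locus mixed-model association scan.

The engine follows the efficient exact-MLM design: eigendecompose the
kinship matrix once, rotate phenotype, covariates and markers into the
eigenbasis (where the covariance is diagonal), and maximize the restricted
likelihood over the variance ratio delta = sigma_e^2 / sigma_g^2 separately
for every marker (no population-parameters-previously-determined
approximation).  Per-marker inference is a two-sided Wald t-test on the
allele-substitution effect; significance uses the p < 1/m rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import EigenK, RemlResult, fit_reml
from .lod import pval_to_lod
from .panel import GenotypePanel
from .popgen import KinshipMatrix

log = logging.getLogger(__name__)

__all__ = ["MixedModelFit", "fit_null_mlm", "scan_single_locus", "results_frame"]

RESULT_COLUMNS = [
    "trait", "marker_id", "chrom", "pos", "ref", "alt", "method",
    "effect", "se", "p_value", "lod", "pve", "significant",
]


@dataclass
class MixedModelFit:
    sigma_g2: float
    sigma_e2: float
    delta: float
    loglik_reml: float
    beta: np.ndarray
    eigen: EigenK

    @property
    def heritability(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


def _as_matrix(K) -> np.ndarray:
    return K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)


def fit_null_mlm(y, X, K) -> MixedModelFit:
    """REML fit of the no-marker model y = X b + u + e, u ~ N(0, sg^2 K).

    delta is optimized on [1e-5, 1e5] by a 100-point log-grid bracket plus
    Brent refinement; sigma_g^2 and sigma_e^2 are recovered from delta and
    the profiled variance.
    """
    res: RemlResult = fit_reml(y, X, K=_as_matrix(K))
    return MixedModelFit(
        sigma_g2=res.sigma_g2,
        sigma_e2=res.sigma_e2,
        delta=res.delta,
        loglik_reml=res.loglik,
        beta=res.beta,
        eigen=res.eigen,
    )


def results_frame(panel: GenotypePanel, idx, trait, method, effect, se, p, vy,
                  threshold=None, significant=None) -> pd.DataFrame:
    """Assemble the shared association-result table for a set of markers."""
    idx = np.asarray(idx, dtype=int)
    effect = np.asarray(effect, dtype=float)
    p = np.asarray(p, dtype=float)
    var_x = np.nanvar(panel.dosage[:, idx], axis=0) if idx.size else np.array([])
    pve = np.minimum(effect**2 * var_x / vy, 1.0) if vy > 0 else np.zeros_like(effect)
    lod = pval_to_lod(np.clip(p, 1e-300, 1.0)) if idx.size else np.array([])
    if significant is None:
        significant = p < threshold if threshold is not None else np.zeros(idx.size, bool)
    return pd.DataFrame({
        "trait": trait,
        "marker_id": panel.marker_ids[idx],
        "chrom": panel.chrom[idx],
        "pos": panel.pos[idx],
        "ref": panel.ref[idx],
        "alt": panel.alt[idx],
        "method": method,
        "effect": effect,
        "se": np.asarray(se, dtype=float),
        "p_value": p,
        "lod": np.atleast_1d(lod),
        "pve": pve,
        "significant": np.asarray(significant, dtype=bool),
    }, columns=RESULT_COLUMNS)


def _chunk_scan(yt, Xt, d, Gt, grid_log10, refine):
    """Exact-MLM statistics for one chunk of rotated markers.

    Returns (effect, schur, rss, delta) at the per-marker REML-optimal delta.
    The delta grid is shared across markers; a quadratic interpolation on the
    log-scale around each marker's best grid point refines the optimum, and
    the refined point is kept only where it improves the criterion.
    """
    n, q = Xt.shape
    m = Gt.shape[1]
    nq1 = n - q - 1
    n_grid = grid_log10.size

    crit = np.full((n_grid, m), -np.inf)
    bx_all = np.zeros((n_grid, m))
    schur_all = np.zeros((n_grid, m))
    rss_all = np.full((n_grid, m), np.nan)

    def _stats_shared(delta):
        w = 1.0 / (d + delta)
        XtW = Xt * w[:, None]
        A = Xt.T @ XtW
        Ainv = np.linalg.inv(A)
        b = XtW.T @ yt
        beta0 = Ainv @ b
        yWy = w @ yt**2
        rss0 = yWy - b @ beta0
        s_xx = (Gt**2 * w[:, None]).sum(axis=0)
        s_xX = Gt.T @ XtW
        s_xy = Gt.T @ (w * yt)
        u = s_xX @ Ainv
        schur = s_xx - np.einsum("mq,mq->m", u, s_xX)
        ok = schur > 1e-12 * np.maximum(s_xx, 1e-300)
        schur_safe = np.where(ok, schur, 1.0)
        bx = np.where(ok, (s_xy - s_xX @ beta0) / schur_safe, 0.0)
        rss = np.maximum(rss0 - bx**2 * schur_safe * ok, 1e-300)
        _, logdetA = np.linalg.slogdet(A)
        sum_log = float(np.log(d + delta).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            c = -0.5 * (nq1 * np.log(rss / nq1) + sum_log + logdetA
                        + np.where(ok, np.log(schur_safe), np.inf))
        return c, bx, np.where(ok, schur, 0.0), rss

    for g, lg in enumerate(grid_log10):
        crit[g], bx_all[g], schur_all[g], rss_all[g] = _stats_shared(10.0**lg)

    best = np.argmax(crit, axis=0)
    cols = np.arange(m)
    eff = bx_all[best, cols]
    schur = schur_all[best, cols]
    rss = rss_all[best, cols]
    delta = 10.0 ** grid_log10[best]
    best_crit = crit[best, cols]

    if refine and n_grid >= 3:
        k = np.clip(best, 1, n_grid - 2)
        c1, c2, c3 = crit[k - 1, cols], crit[k, cols], crit[k + 1, cols]
        h = grid_log10[1] - grid_log10[0]
        denom = c1 - 2 * c2 + c3
        with np.errstate(divide="ignore", invalid="ignore"):
            shift = np.where(denom < -1e-12, 0.5 * h * (c1 - c3) / denom, 0.0)
        lg_star = np.clip(grid_log10[k] + shift, grid_log10[k - 1], grid_log10[k + 1])
        delta_star = 10.0**lg_star

        # one batched evaluation at the per-marker refined delta
        w = 1.0 / (d[:, None] + delta_star[None, :])          # (n, m)
        s_xx = (Gt**2 * w).sum(axis=0)
        wy = w * yt[:, None]
        s_xy = (Gt * wy).sum(axis=0)
        A = np.einsum("ip,im,iq->mpq", Xt, w, Xt)
        b = np.einsum("ip,im,i->mp", Xt, w, yt)
        sxX = np.einsum("im,ip,im->mp", Gt, Xt, w)
        Ainv = np.linalg.inv(A)
        beta0 = np.einsum("mpq,mq->mp", Ainv, b)
        u = np.einsum("mpq,mq->mp", Ainv, sxX)
        schur_r = s_xx - np.einsum("mp,mp->m", u, sxX)
        ok = schur_r > 1e-12 * np.maximum(s_xx, 1e-300)
        schur_safe = np.where(ok, schur_r, 1.0)
        bx_r = np.where(ok, (s_xy - np.einsum("mp,mp->m", sxX, beta0)) / schur_safe, 0.0)
        yWy = (wy * yt[:, None]).sum(axis=0)
        rss0 = yWy - np.einsum("mp,mp->m", b, beta0)
        rss_r = np.maximum(rss0 - bx_r**2 * schur_safe * ok, 1e-300)
        sign, logdetA = np.linalg.slogdet(A)
        sum_log = np.log(d[:, None] + delta_star[None, :]).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            crit_r = -0.5 * (nq1 * np.log(rss_r / nq1) + sum_log + logdetA
                             + np.where(ok, np.log(schur_safe), np.inf))
        take = crit_r > best_crit
        eff = np.where(take, bx_r, eff)
        schur = np.where(take, np.where(ok, schur_r, 0.0), schur)
        rss = np.where(take, rss_r, rss)
        delta = np.where(take, delta_star, delta)

    return eff, schur, rss, delta


def scan_single_locus(y, X, K, panel: GenotypePanel, *, fit: MixedModelFit | None = None,
                      n_grid: int = 21, refine: bool = True, trait: str = "trait",
                      chunk: int = 20_000) -> pd.DataFrame:
    """Exact mixed-model scan of every marker in the panel.

    For each marker the variance ratio delta is re-optimized under the
    augmented model [X, x_j]; the effect and its standard error come from
    the generalized least-squares fit at that optimum, tested two-sided
    against t with n - q - 1 degrees of freedom.  Constant markers get
    p = 1 and zero effect.  Markers are declared significant at p < 1/m.
    """
    if not panel.is_complete:
        raise ValueError("panel has missing calls; impute before scanning")
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, q = X.shape
    if fit is None:
        fit = fit_null_mlm(y, X, K)
    d, U = fit.eigen.d, fit.eigen.U
    yt = U.T @ y
    Xt = U.T @ X
    m = panel.n_markers
    nq1 = n - q - 1
    grid_log10 = np.linspace(-5.0, 5.0, n_grid)

    effect = np.zeros(m)
    se = np.zeros(m)
    p = np.ones(m)
    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        Gt = U.T @ panel.dosage[:, sl]
        eff, schur, rss, _ = _chunk_scan(yt, Xt, d, Gt, grid_log10, refine)
        sg2 = rss / nq1
        ok = schur > 0
        if (~ok).any():
            log.info("%d constant/collinear markers set to p=1 in chunk", int((~ok).sum()))
        se_c = np.where(ok, np.sqrt(sg2 / np.where(ok, schur, 1.0)), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(ok, eff / se_c, 0.0)
        p_c = np.where(ok, 2.0 * stats.t.sf(np.abs(tstat), df=nq1), 1.0)
        effect[sl] = np.where(ok, eff, 0.0)
        se[sl] = se_c
        p[sl] = p_c

    return results_frame(panel, np.arange(m), trait, "single_mlm",
                         effect, se, p, vy=float(y.var()), threshold=1.0 / m)
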