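"""Multi-locus association engines.

Three scanners share the result schema of :mod:`starchgwas.mlm_single`:

* :func:`scan_fastmremma` — a two-stage scan: markers are screened as
  single random effects against the whitened polygenic background, and the
  retained set is fitted jointly with per-marker normal priors whose
  variances are estimated by an expectation-maximization empirical-Bayes
  loop; significance is LOD > 3 from the likelihood ratio of dropping a
  marker.
* :func:`scan_farmcpu` — iterates a fixed-effect scan (pseudo-QTNs as
  covariates) with a random-effect model over binned candidate pseudo-QTNs
  until the pseudo-QTN set stabilizes; significance is p < 1/m on the final
  fixed-effect scan.
* :func:`scan_lasso` — an L1-penalized multi-marker regression (penalty
  chosen by cross-validation) followed by a Wald test built from a
  ridge-type curvature approximation to the effect variances on the active
  set; significance is LOD > 3.

Because all markers compete within one model, the multi-locus engines need
no multiple-testing correction; the LOD <-> p bridge of
:mod:`starchgwas.lod` makes their LOD > 3 rule commensurable with the
single-locus p-value thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from ._reml import eigen_k, fit_reml
from .lod import lod_to_pval, pval_to_lod
from .mlm_single import fit_null_mlm, results_frame
from .panel import GenotypePanel

log = logging.getLogger(__name__)

__all__ = [
    "scan_fastmremma",
    "scan_farmcpu",
    "scan_lasso",
    "fit_lasso",
    "glm_scan",
    "pval_to_lod",
    "lod_to_pval",
]


# ----------------------------------------------------------------------
# Shared fixed-effect scan
# ----------------------------------------------------------------------

def glm_scan(y: np.ndarray, C: np.ndarray, G: np.ndarray):
    """Per-marker fixed-effect regression of y on each column of G given C.

    Returns (effect, se, p).  Covariates are projected out of y and G; the
    marker test is then a simple regression with n - ncol(C) - 1 residual
    degrees of freedom.  Constant/collinear markers get p = 1, effect 0.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    Q, _ = np.linalg.qr(C)
    My = y - Q @ (Q.T @ y)
    MG = G - Q @ (Q.T @ G)
    ss = (MG**2).sum(axis=0)
    ok = ss > 1e-10 * n
    ss_safe = np.where(ok, ss, 1.0)
    beta = np.where(ok, MG.T @ My / ss_safe, 0.0)
    rss = np.maximum(My @ My - beta**2 * ss_safe, 0.0)
    df = n - C.shape[1] - 1
    sigma2 = rss / df
    se = np.sqrt(sigma2 / ss_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok & (se > 0), beta / se, 0.0)
    p = np.where(ok, 2.0 * stats.t.sf(np.abs(t), df=df), 1.0)
    return beta, np.where(ok, se, np.nan), p


# ----------------------------------------------------------------------
# Two-stage EM empirical-Bayes engine
# ----------------------------------------------------------------------

def _marginal_loglik(r: np.ndarray, Z: np.ndarray, sig2: np.ndarray, se2: float) -> float:
    """Gaussian marginal log-likelihood of r ~ N(0, se2 I + Z diag(sig2) Z')."""
    n = r.size
    keep = np.flatnonzero(sig2 > 0)
    if keep.size == 0:
        return -0.5 * (n * math.log(2 * math.pi * se2) + (r @ r) / se2)
    Zk = Z[:, keep]
    s = sig2[keep]
    M = np.diag(1.0 / s) + Zk.T @ Zk / se2
    sign, logdet_m = np.linalg.slogdet(M)
    logdet_v = n * math.log(se2) + logdet_m + float(np.log(s).sum())
    zr = Zk.T @ r
    quad = ((r @ r) - zr @ np.linalg.solve(M, zr) / se2) / se2
    return -0.5 * (n * math.log(2 * math.pi) + logdet_v + quad)


def _emeb(r: np.ndarray, Z: np.ndarray, tol: float = 1e-6, max_iter: int = 1000):
    """EM empirical-Bayes fit of r = Z gamma + eps, gamma_s ~ N(0, sigma_s^2).

    Returns (mu, post_var, sig2, se2, converged): posterior means/variances
    of the marker effects and the estimated variance components.
    """
    n, k = Z.shape
    vr = float(r.var()) or 1.0
    sig2 = np.full(k, 0.5 * vr / max(k, 1) + 1e-8)
    se2 = 0.5 * vr + 1e-8
    ZtZ = Z.T @ Z
    Ztr = Z.T @ r
    converged = False
    for _ in range(max_iter):
        A = ZtZ / se2 + np.diag(1.0 / sig2)
        Sigma = np.linalg.inv(A)
        mu = Sigma @ Ztr / se2
        new_sig2 = np.maximum(mu**2 + np.diag(Sigma), 1e-12)
        resid = r - Z @ mu
        new_se2 = float((resid @ resid + np.einsum("st,ts->", Sigma, ZtZ)) / n)
        new_se2 = max(new_se2, 1e-12)
        rel = max(
            float(np.max(np.abs(new_sig2 - sig2) / np.maximum(sig2, 1e-12))),
            abs(new_se2 - se2) / max(se2, 1e-12),
        )
        sig2, se2 = new_sig2, new_se2
        if rel < tol:
            converged = True
            break
    A = ZtZ / se2 + np.diag(1.0 / sig2)
    Sigma = np.linalg.inv(A)
    mu = Sigma @ Ztr / se2
    return mu, np.diag(Sigma).copy(), sig2, se2, converged


def scan_fastmremma(y, X, K, panel: GenotypePanel, stage1_alpha: float = 0.005,
                    trait: str = "trait", max_selected: int | None = None) -> pd.DataFrame:
    """Two-stage multi-locus scan (random-effect screen + EM empirical Bayes).

    Stage 1 whitens y, X and the markers by the null polygenic covariance
    (sigma_g^2 K + sigma_e^2 I)^(-1/2), removes the covariate subspace, and
    screens each marker with the 1-df score/Wald test of its variance
    component; markers with stage-1 p <= ``stage1_alpha`` are retained.
    Stage 2 fits the retained markers jointly with per-marker normal priors
    estimated by EM empirical Bayes, and assigns each marker the LOD of the
    likelihood ratio of dropping it from the fitted covariance.  Markers
    with LOD > 3 are significant.  An empty stage-1 set yields an empty
    result, not an error.
    """
    if not panel.is_complete:
        raise ValueError("panel has missing calls; impute before scanning")
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    n, q = X.shape
    if n < 10:
        raise ValueError("need at least 10 lines")
    fit = fit_null_mlm(y, X, K)
    d, U = fit.eigen.d, fit.eigen.U
    scale = 1.0 / np.sqrt(fit.sigma_g2 * d + fit.sigma_e2)
    # whiten, then move to the orthogonal complement of the covariates
    yw = scale * (U.T @ y)
    Xw = scale[:, None] * (U.T @ X)
    Gw = scale[:, None] * (U.T @ panel.dosage)
    N = linalg.null_space(Xw.T)          # n x (n - q), orthonormal
    r = N.T @ yw
    Z = N.T @ Gw

    # stage 1: per-marker screen on the whitened residual space
    ss = (Z**2).sum(axis=0)
    ok = ss > 1e-10
    ss_safe = np.where(ok, ss, 1.0)
    beta = np.where(ok, Z.T @ r / ss_safe, 0.0)
    rss = np.maximum(r @ r - beta**2 * ss_safe, 1e-300)
    df1 = r.size - 1
    tstat = beta / np.sqrt(rss / df1 / ss_safe)
    p1 = np.where(ok, 2.0 * stats.t.sf(np.abs(tstat), df=df1), 1.0)
    selected = np.flatnonzero(p1 <= stage1_alpha)
    cap = max_selected if max_selected is not None else min(int(0.5 * n), 200)
    if selected.size > cap:
        log.warning("stage 1 retained %d markers; keeping the %d smallest p",
                    selected.size, cap)
        selected = selected[np.argsort(p1[selected])[:cap]]
    out_empty = results_frame(panel, np.array([], int), trait, "fastmremma",
                              np.array([]), np.array([]), np.array([]), vy=float(y.var()))
    out_empty.attrs["stage1_pvalues"] = p1
    if selected.size == 0:
        return out_empty

    # stage 2: joint empirical-Bayes fit of the retained markers
    Zs = Z[:, selected]
    mu, post_var, sig2, se2, converged = _emeb(r, Zs)
    if not converged:
        log.info("EM empirical Bayes hit the iteration cap; best iterate returned")
    ll_full = _marginal_loglik(r, Zs, sig2, se2)
    lods = np.empty(selected.size)
    for i in range(selected.size):
        sig2_drop = sig2.copy()
        sig2_drop[i] = 0.0
        lods[i] = max(0.0, (ll_full - _marginal_loglik(r, Zs, sig2_drop, se2)) / math.log(10))
    p2 = lod_to_pval(lods)
    out = results_frame(panel, selected, trait, "fastmremma",
                        mu, np.sqrt(post_var), p2, vy=float(y.var()),
                        significant=lods > 3.0)
    out["lod"] = lods
    out.attrs["stage1_pvalues"] = p1
    out.attrs["em_converged"] = converged
    return out


# ----------------------------------------------------------------------
# Iterative pseudo-QTN (FarmCPU-style) engine
# ----------------------------------------------------------------------

def _scan_with_pseudo(y, X, G, pseudo: np.ndarray, ld_r2_max: float):
    """Fixed-effect scan with pseudo-QTN covariates and the LD-conflict rule.

    A marker is never tested against itself, and pseudo-QTN covariates in
    LD (r^2 > ``ld_r2_max``) with the tested marker are dropped for that
    marker's test.
    """
    n, m = G.shape
    C = np.hstack([X, G[:, pseudo]]) if pseudo.size else X
    effect, se, p = glm_scan(y, C, G)
    if pseudo.size == 0:
        return effect, se, p
    # markers needing a reduced covariate set
    Gp = G[:, pseudo]
    Gc = (G - G.mean(axis=0)) / np.where(G.std(axis=0) > 0, G.std(axis=0), 1.0)
    Pc = (Gp - Gp.mean(axis=0)) / np.where(Gp.std(axis=0) > 0, Gp.std(axis=0), 1.0)
    r2 = (Pc.T @ Gc / n) ** 2                      # (k, m)
    conflict = r2 > ld_r2_max
    conflict[np.arange(pseudo.size), pseudo] = True
    redo = np.flatnonzero(conflict.any(axis=0))
    for j in redo:
        keep = pseudo[~conflict[:, j]]
        Cj = np.hstack([X, G[:, keep]]) if keep.size else X
        e_j, s_j, p_j = glm_scan(y, Cj, G[:, [j]])
        effect[j], se[j], p[j] = e_j[0], s_j[0], p_j[0]
    return effect, se, p


def _select_pseudo_qtns(y, X, panel, p: np.ndarray, bin_sizes, n_candidates,
                        qtn_threshold: float):
    """Choose the pseudo-QTN set maximizing the restricted likelihood of a
    random-effect model whose relationship matrix is built from candidates."""
    cand_mask = p <= qtn_threshold
    if not cand_mask.any():
        return None
    best_ll, best_set = -np.inf, None
    for bsize in bin_sizes:
        bin_id = panel.chrom * (2**40) + panel.pos // int(bsize)
        order = np.argsort(p, kind="stable")
        seen_bins: set[int] = set()
        reps = []
        for j in order:
            if not cand_mask[j]:
                break  # sorted by p; once above threshold all later ones are too
            b = int(bin_id[j])
            if b not in seen_bins:
                seen_bins.add(b)
                reps.append(j)
        if not reps:
            continue
        for t in n_candidates:
            cand = np.array(sorted(reps[:t]), dtype=int)
            if cand.size == 0:
                continue
            Gc = panel.dosage[:, cand]
            sd = Gc.std(axis=0)
            ok = sd > 0
            if not ok.any():
                continue
            Wc = (Gc[:, ok] - Gc[:, ok].mean(axis=0)) / sd[ok]
            Kc = Wc @ Wc.T / ok.sum()
            try:
                ll = fit_reml(y, X, K=Kc).loglik
            except np.linalg.LinAlgError:  # pragma: no cover - degenerate candidates
                continue
            if ll > best_ll:
                best_ll, best_set = ll, cand
    return best_set


def scan_farmcpu(y, X, panel: GenotypePanel, max_iter: int = 10,
                 bin_sizes=(500_000, 5_000_000, 50_000_000),
                 n_candidates=(5, 10, 15), qtn_threshold: float = 0.01,
                 start_threshold: float | None = None,
                 ld_r2_max: float = 0.7, trait: str = "trait") -> pd.DataFrame:
    """Iterative fixed/random-effect scan with pseudo-QTN covariates.

    Each iteration (a) scans every marker in a fixed-effect model with the
    current pseudo-QTNs plus the structure covariates, and (b) re-selects
    the pseudo-QTN set: markers are binned by position at each bin size,
    the best marker per bin (by scan p-value, among markers with
    p <= ``qtn_threshold``) represents the bin, and the candidate set (top
    5/10/15 bins per bin size) that maximizes the restricted likelihood of
    a random-effect model built from the candidates is adopted.  Iteration
    stops when the pseudo-QTN set repeats (oscillations stop at
    ``max_iter`` with a flag); the final fixed-effect scan is reported with
    significance at p < 1/m.  Iteration 1 (no pseudo-QTNs) is exactly the
    plain fixed-effect scan with structure covariates; per the method's
    published default, the iteration only starts at all when some marker
    reaches ``start_threshold`` (0.01/m unless overridden) on that first
    scan, which keeps null phenotypes from accruing noise pseudo-QTNs.
    """
    if not panel.is_complete:
        raise ValueError("panel has missing calls; impute before scanning")
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    G = panel.dosage
    m = panel.n_markers
    if start_threshold is None:
        start_threshold = 0.01 / m
    pseudo = np.array([], dtype=int)
    history: list[tuple[int, ...]] = []
    oscillating = False
    for it in range(max_iter):
        effect, se, p = _scan_with_pseudo(y, X, G, pseudo, ld_r2_max)
        if it == 0 and p.min() > start_threshold:
            break
        new = _select_pseudo_qtns(y, X, panel, p, bin_sizes, n_candidates, qtn_threshold)
        if new is None or tuple(new) == tuple(pseudo):
            break
        if tuple(new) in history:
            oscillating = True
            log.warning("pseudo-QTN set oscillates; stopping")
            break
        history.append(tuple(pseudo))
        pseudo = new
    out = results_frame(panel, np.arange(m), trait, "farmcpu",
                        effect, se, p, vy=float(y.var()), threshold=1.0 / m)
    out.attrs["pseudo_qtns"] = pseudo.tolist()
    out.attrs["pseudo_qtn_history"] = [list(h) for h in history]
    out.attrs["oscillating"] = oscillating
    return out


# ----------------------------------------------------------------------
# L1-penalized engine with Wald significance
# ----------------------------------------------------------------------

def fit_lasso(Xstd: np.ndarray, y: np.ndarray, alpha: float | None = None,
              cv_folds: int = 5, seed: int = 0, n_alphas: int = 100):
    """L1 path fit; returns (alpha, coef).

    With ``alpha=None`` the penalty is chosen by ``cv_folds``-fold
    cross-validation (minimum mean squared prediction error, seeded fold
    split); the solution at the chosen penalty is then re-solved to high
    precision.  ``alpha=0`` is the unpenalized (OLS) limit, only valid for
    m < n.  The objective is (1/2n)||y - X b||^2 + alpha ||b||_1.
    """
    from sklearn.linear_model import Lasso, LassoCV
    from sklearn.model_selection import KFold

    n, m = Xstd.shape
    if alpha == 0:
        if m >= n:
            raise ValueError("alpha=0 requires fewer markers than lines")
        coef, *_ = np.linalg.lstsq(Xstd, y, rcond=None)
        return 0.0, coef
    if alpha is None:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        # the CV stage only has to locate the MSE-minimizing penalty, so it
        # runs at a loose tolerance; the solution itself is re-solved below
        las = LassoCV(alphas=n_alphas, eps=1e-2, cv=cv, fit_intercept=False,
                      max_iter=20_000, tol=1e-3)
        las.fit(Xstd, y)
        alpha = float(las.alpha_)
    final = Lasso(alpha=alpha, fit_intercept=False, max_iter=500_000, tol=1e-12)
    final.fit(Xstd, y)
    return alpha, final.coef_.copy()


def scan_lasso(y, X, panel: GenotypePanel, cv_folds: int = 5, seed: int = 0,
               alpha: float | None = None, trait: str = "trait") -> pd.DataFrame:
    """L1-penalized multi-marker scan with ridge-curvature Wald significance.

    Covariates are projected out of the phenotype and of every marker;
    markers are standardized internally and the active set of the
    cross-validated L1 solution receives approximate effect variances from
    the sandwich

        Var(b_S) ~ sigma_e^2 [(Xs'Xs + lambda n I)^-1 Xs'Xs (Xs'Xs + lambda n I)^-1]

    whose diagonal feeds a Wald z -> p -> LOD test (LOD > 3 significant).
    An empty active set yields an empty result.  The Wald recipe is
    isolated here so an alternative significance scheme can be swapped in.
    """
    if not panel.is_complete:
        raise ValueError("panel has missing calls; impute before scanning")
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    n = y.size
    Q, _ = np.linalg.qr(X)
    yres = y - Q @ (Q.T @ y)
    G = panel.dosage
    Gres = G - Q @ (Q.T @ G)
    sd = Gres.std(axis=0)
    poly = np.flatnonzero(sd > 1e-10)
    if poly.size == 0:
        return results_frame(panel, np.array([], int), trait, "lasso",
                             np.array([]), np.array([]), np.array([]), vy=float(y.var()))
    Gs = Gres[:, poly] / sd[poly]
    lam, coef = fit_lasso(Gs, yres, alpha=alpha, cv_folds=cv_folds, seed=seed)
    active = np.flatnonzero(coef != 0.0)
    if active.size == 0:
        out = results_frame(panel, np.array([], int), trait, "lasso",
                            np.array([]), np.array([]), np.array([]), vy=float(y.var()))
        out.attrs["lambda"] = lam
        return out
    Xs = Gs[:, active]
    b = coef[active]
    resid = yres - Xs @ b
    dof = max(n - X.shape[1] - active.size, 1)
    sigma_e2 = float(resid @ resid) / dof
    XtX = Xs.T @ Xs
    M = XtX + lam * n * np.eye(active.size)
    Minv = np.linalg.inv(M)
    cov = sigma_e2 * (Minv @ XtX @ Minv)
    se_std = np.sqrt(np.maximum(np.diag(cov), 1e-300))
    z = b / se_std
    p = 2.0 * stats.norm.sf(np.abs(z))
    lods = pval_to_lod(np.clip(p, 1e-300, 1.0))
    idx = poly[active]
    scale = sd[poly][active]
    out = results_frame(panel, idx, trait, "lasso",
                        b / scale, se_std / scale, p, vy=float(y.var()),
                        significant=np.atleast_1d(lods) > 3.0)
    out.attrs["lambda"] = lam
    return out
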