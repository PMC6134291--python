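"""Multi-locus engines: two-stage EM empirical Bayes, iterative pseudo-QTN,
and L1 with Wald significance."""

import numpy as np
import pytest

import starchgwas as sg
from starchgwas.multilocus import fit_lasso, glm_scan


@pytest.fixture(scope="module")
def qtl_panel():
    """230-line, 1000-marker panel used by the power-style checks."""
    return sg.simulate_genotype_panel(n=230, m=1000, n_subpops=2, seed=29)


@pytest.fixture(scope="module")
def qtl_setup(qtl_panel):
    K = sg.compute_kinship(qtl_panel)
    pcs = sg.compute_pca(qtl_panel, k=5)
    X = np.column_stack([np.ones(230), pcs.scores])
    return qtl_panel, K, X


def _qtl_phenotype(panel, j, pve, rng):
    x = panel.dosage[:, j]
    a = np.sqrt(pve / ((1 - pve) * x.var()))
    return a * x + rng.standard_normal(panel.n_lines)


# ----------------------------------------------------------------------
# LOD <-> p bridge
# ----------------------------------------------------------------------

def test_lod_bridge_endpoints_and_roundtrip():
    assert sg.pval_to_lod(1.0) == 0.0
    assert sg.lod_to_pval(3.0) == pytest.approx(2.0e-4, abs=5e-6)
    for p in (1e-2, 1e-6):
        assert sg.lod_to_pval(sg.pval_to_lod(p)) == pytest.approx(p, rel=1e-12)
    assert np.isinf(sg.pval_to_lod(0.0))
    with pytest.raises(ValueError):
        sg.pval_to_lod(1.5)


# ----------------------------------------------------------------------
# Two-stage EM empirical Bayes
# ----------------------------------------------------------------------

def test_fastmremma_null_yields_almost_no_calls():
    panel = sg.simulate_genotype_panel(n=230, m=2000, n_subpops=2, seed=41)
    K = sg.compute_kinship(panel)
    pcs = sg.compute_pca(panel, k=5)
    X = np.column_stack([np.ones(230), pcs.scores])
    rng = np.random.default_rng(7)
    total = 0
    for _ in range(40):
        y = rng.standard_normal(230)
        total += int(sg.scan_fastmremma(y, X, K, panel)["significant"].sum())
    assert total / 40 < 0.5


def test_fastmremma_detects_strong_qtl(qtl_setup):
    panel, K, X = qtl_setup
    rng = np.random.default_rng(3)
    hits = 0
    reps = 60
    for _ in range(reps):
        y = _qtl_phenotype(panel, 555, 0.20, rng)
        res = sg.scan_fastmremma(y, X, K, panel)
        det = res[res["significant"]]
        hits += (det.index.size > 0) and (panel.pos[555] in det["pos"].values)
    assert hits / reps >= 0.90


def test_fastmremma_empty_stage1_returns_empty(qtl_setup):
    panel, K, X = qtl_setup
    rng = np.random.default_rng(11)
    y = rng.standard_normal(230)
    res = sg.scan_fastmremma(y, X, K, panel, stage1_alpha=1e-12)
    assert len(res) == 0
    assert "stage1_pvalues" in res.attrs


# ----------------------------------------------------------------------
# Iterative pseudo-QTN engine
# ----------------------------------------------------------------------

def test_farmcpu_first_iteration_equals_plain_glm_scan(qtl_setup):
    panel, K, X = qtl_setup
    rng = np.random.default_rng(13)
    y = _qtl_phenotype(panel, 100, 0.15, rng)
    res = sg.scan_farmcpu(y, X, panel, start_threshold=0.0)  # stop after iter 1
    # independent per-marker OLS with the same covariates
    for j in range(0, panel.n_markers, 37):
        C = np.column_stack([X, panel.dosage[:, j]])
        beta, *_ = np.linalg.lstsq(C, y, rcond=None)
        resid = y - C @ beta
        sigma2 = resid @ resid / (230 - C.shape[1])
        cov = sigma2 * np.linalg.inv(C.T @ C)
        from scipy import stats
        t = beta[-1] / np.sqrt(cov[-1, -1])
        p = 2 * stats.t.sf(abs(t), df=230 - C.shape[1])
        assert res["p_value"].iloc[j] == pytest.approx(p, abs=1e-10)
        assert res["effect"].iloc[j] == pytest.approx(beta[-1], abs=1e-10)


def test_farmcpu_recovers_two_unlinked_qtls(qtl_panel):
    panel = qtl_panel
    pcs = sg.compute_pca(panel, k=5)
    X = np.column_stack([np.ones(230), pcs.scores])
    j1, j2 = 100, 800  # different chromosomes -> negligible LD
    x1, x2 = panel.dosage[:, j1], panel.dosage[:, j2]
    a1 = np.sqrt(0.10 / (0.80 * x1.var()))
    a2 = np.sqrt(0.10 / (0.80 * x2.var()))
    rng = np.random.default_rng(17)
    both = 0
    reps = 50
    for _ in range(reps):
        y = a1 * x1 + a2 * x2 + rng.standard_normal(230)
        res = sg.scan_farmcpu(y, X, panel)
        pseudo = set(res.attrs["pseudo_qtns"])
        both += {j1, j2} <= pseudo
    assert both / reps >= 0.70


def test_farmcpu_null_calibration(qtl_setup):
    """Fraction of null markers below 1/m stays at the calibrated level
    (within 3 binomial standard errors of 1/m)."""
    panel, K, X = qtl_setup
    rng = np.random.default_rng(19)
    m = panel.n_markers
    frac = []
    for _ in range(60):
        y = rng.standard_normal(230)
        res = sg.scan_farmcpu(y, X, panel)
        frac.append(res["significant"].mean())
    expectation = 1.0 / m
    se = np.sqrt(expectation / (60 * m))
    assert np.mean(frac) <= expectation + 3 * se


def test_farmcpu_stops_on_repeat_or_max_iter(qtl_setup):
    panel, K, X = qtl_setup
    rng = np.random.default_rng(23)
    y = _qtl_phenotype(panel, 300, 0.2, rng)
    res = sg.scan_farmcpu(y, X, panel, max_iter=2)
    assert "pseudo_qtns" in res.attrs and isinstance(res.attrs["oscillating"], bool)


# ----------------------------------------------------------------------
# L1 engine
# ----------------------------------------------------------------------

def test_lasso_unpenalized_limit_equals_ols():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((50, 5))
    beta = np.array([1.0, 0.0, -0.5, 0.0, 0.25])
    y = X @ beta + 0.1 * rng.standard_normal(50)
    _, coef = fit_lasso(X, y, alpha=0.0)
    ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.allclose(coef, ols, atol=1e-6)


def _kkt_violation(X, y, alpha, coef):
    n = X.shape[0]
    grad = X.T @ (y - X @ coef) / n
    active = coef != 0
    v_active = np.abs(grad[active] - alpha * np.sign(coef[active])).max() if active.any() else 0.0
    v_inactive = max(0.0, np.abs(grad[~active]).max() - alpha) if (~active).any() else 0.0
    return max(v_active, v_inactive)


@pytest.mark.parametrize("seed", range(5))
def test_lasso_satisfies_kkt_and_matches_qp_oracle(seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((20, 50))
    y = X[:, 0] - 0.7 * X[:, 3] + 0.3 * rng.standard_normal(20)
    alpha_max = np.abs(X.T @ y).max() / 20
    alpha = 0.3 * alpha_max
    _, coef = fit_lasso(X, y, alpha=alpha)
    assert _kkt_violation(X, y, alpha, coef) < 1e-6
    # active-set equality-constrained QP oracle
    A = np.flatnonzero(coef)
    s = np.sign(coef[A])
    XA = X[:, A]
    oracle = np.linalg.solve(XA.T @ XA, XA.T @ y - 20 * alpha * s)
    assert np.allclose(coef[A], oracle, atol=1e-6)


def test_lasso_detects_strong_qtl_with_shrinkage(qtl_setup):
    panel, K, X = qtl_setup
    rng = np.random.default_rng(37)
    hits, shrunk, checked = 0, 0, 0
    reps = 40
    for r in range(reps):
        y = _qtl_phenotype(panel, 222, 0.20, rng)
        res = sg.scan_lasso(y, X, panel, seed=r)
        det = res[res["significant"]]
        row = res[res["pos"] == panel.pos[222]]
        hits += len(det) > 0 and panel.pos[222] in det["pos"].values
        if len(row):
            # compare against the OLS refit restricted to the active set
            Q, _ = np.linalg.qr(X)
            yres = y - Q @ (Q.T @ y)
            active_pos = res["pos"].to_numpy()
            cols = [int(np.flatnonzero(panel.pos == p)[0]) for p in active_pos]
            Ga = panel.dosage[:, cols] - Q @ (Q.T @ panel.dosage[:, cols])
            ols, *_ = np.linalg.lstsq(Ga, yres, rcond=None)
            k = int(np.flatnonzero(active_pos == panel.pos[222])[0])
            checked += 1
            shrunk += abs(row["effect"].iloc[0]) <= abs(ols[k]) + 1e-8
    assert hits / reps >= 0.80
    assert shrunk / max(checked, 1) >= 0.9


def test_lasso_empty_active_set_returns_empty(qtl_setup):
    panel, K, X = qtl_setup
    rng = np.random.default_rng(41)
    y = rng.standard_normal(230)
    res = sg.scan_lasso(y, X, panel, alpha=1e6)
    assert len(res) == 0


# ----------------------------------------------------------------------
# Cross-engine invariants
# ----------------------------------------------------------------------

def test_sign_consistency_across_engines(qtl_setup):
    """Engines that detect a dominant-signal QTL agree on the effect sign."""
    panel, K, X = qtl_setup
    rng = np.random.default_rng(43)
    j = 444
    for rep in range(6):
        x = panel.dosage[:, j]
        a = np.sqrt(0.25 / (0.75 * x.var()))
        y = a * x + rng.standard_normal(230)
        signs = []
        for res in (
            sg.scan_single_locus(y, X, K, panel),
            sg.scan_fastmremma(y, X, K, panel),
            sg.scan_farmcpu(y, X, panel),
            sg.scan_lasso(y, X, panel, seed=rep),
        ):
            det = res[(res["significant"]) & (res["pos"] == panel.pos[j])]
            if len(det):
                signs.append(np.sign(det["effect"].iloc[0]))
        assert len(signs) >= 2 and len(set(signs)) == 1
        assert signs[0] > 0


def test_multilocus_selectivity_versus_naive_glm(qtl_setup):
    """On null data, the multi-locus engines call far fewer markers than the
    count of p < 0.05 hits from a naive per-marker regression."""
    panel, K, X = qtl_setup
    rng = np.random.default_rng(47)
    y = rng.standard_normal(230)
    _, _, p_naive = glm_scan(y, np.ones((230, 1)), panel.dosage)
    naive = int((p_naive < 0.05).sum())
    multi = (
        int(sg.scan_fastmremma(y, X, K, panel)["significant"].sum())
        + int(sg.scan_farmcpu(y, X, panel)["significant"].sum())
        + int(sg.scan_lasso(y, X, panel, seed=0)["significant"].sum())
    )
    assert multi < naive
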