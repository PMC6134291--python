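"""Synthetic panel generator and phenotype simulator."""

import numpy as np
import pytest

import starchgwas as sg
from starchgwas.simdata import (
    calibrate_qtl_effects,
    design_from_yaml,
    design_to_yaml,
)

from conftest import toy_panel

QTL_POSITIONS = [(q.chrom, q.pos) for q in sg.BENCHMARK_QTLS]
QTL_MAFS = [q.maf for q in sg.BENCHMARK_QTLS]


def test_symmetric_dosage_counts_give_maf_half():
    panel = toy_panel([[0], [0], [2], [2]])
    assert panel.maf[0] == pytest.approx(0.5)


def test_required_positions_present(panel230):
    for chrom, pos in QTL_POSITIONS:
        j = panel230.marker_index(chrom, pos)
        assert panel230.chrom[j] == chrom and panel230.pos[j] == pos


def test_required_marker_maf_near_target(panel230):
    idx = [panel230.marker_index(c, p) for c, p in QTL_POSITIONS]
    assert np.all(np.abs(panel230.maf[idx] - np.array(QTL_MAFS)) <= 0.05)


def test_generator_is_deterministic():
    kw = dict(n=25, m=120, n_subpops=2, seed=42,
              chrom_lengths={1: 10_000_000, 2: 10_000_000})
    a = sg.simulate_genotype_panel(**kw)
    b = sg.simulate_genotype_panel(**kw)
    assert np.array_equal(a.dosage, b.dosage)
    assert np.array_equal(a.pos, b.pos) and np.array_equal(a.chrom, b.chrom)


def test_panel_structural_invariants(small_panel):
    small_panel.validate(raw=True)
    assert small_panel.maf.min() >= 0.05
    # stored-vs-recomputed MAF agreement is trivial by construction but the
    # folding at 0.5 must hold
    assert small_panel.maf.max() <= 0.5 + 1e-12


@pytest.mark.parametrize("bad", [
    dict(maf_range=(0.0, 0.5)),
    dict(maf_range=(0.4, 0.2)),
    dict(n=1),
    dict(required_positions=[(1, 999_999_999_999)]),
])
def test_generator_parameter_errors(bad):
    kw = dict(n=10, m=20, seed=0)
    kw.update(bad)
    with pytest.raises((ValueError,)):
        sg.simulate_genotype_panel(**kw)


# ----------------------------------------------------------------------
# Effect calibration
# ----------------------------------------------------------------------

def test_matched_pve_variance_budget(panel230):
    """With 56% QTL PVE, 10% structure and unit variance components, the
    implied total variance solves 0.34 T = 2."""
    design = sg.benchmark_design()
    cal = calibrate_qtl_effects(panel230, design)
    assert cal.total_var == pytest.approx(2.0 / 0.34, rel=1e-12)
    assert cal.structure_var == pytest.approx(0.10 * 2.0 / 0.34, rel=1e-12)
    # each QTL's variance contribution hits its target share exactly
    x = panel230.dosage[:, cal.qtl_idx]
    realized = cal.effects**2 * x.var(axis=0) / cal.total_var
    targets = [q.target_pve for q in design.qtls]
    assert np.allclose(realized, targets, atol=1e-12)


def test_zero_target_pve_gives_zero_effect(panel230):
    qtls = [sg.QTLSpec(1, QTL_POSITIONS[0][1], 0.3, 1.0, 0.0)]
    design = sg.SimulationDesign(qtls=qtls, structure_pve=0.0)
    cal = calibrate_qtl_effects(panel230, design)
    assert cal.effects[0] == 0.0


def test_printed_effects_realized_pve_matches_variance_ratio_oracle(panel230):
    design = sg.benchmark_design(n_reps=5, seed=13, effect_mode="printed_effects")
    K = sg.compute_kinship(panel230)
    pcs = sg.compute_pca(panel230, k=5)
    cal = calibrate_qtl_effects(panel230, design)
    recs = sg.simulate_phenotypes(panel230, design, K, pcs)
    for rec in recs:
        # brute-force per-QTL variance ratio recomputed from the record
        x = panel230.dosage[:, cal.qtl_idx]
        oracle = (cal.effects**2 * x.var(axis=0)) / rec.phenotype.var()
        assert np.allclose(rec.realized_pve, oracle, rtol=1e-10)


def test_calibration_errors(panel230):
    design = sg.benchmark_design()
    missing = sg.SimulationDesign(qtls=[sg.QTLSpec(1, 12345, 0.3, 1.0, 0.1)])
    with pytest.raises(LookupError):
        calibrate_qtl_effects(panel230, missing)
    with pytest.raises(ValueError):
        sg.SimulationDesign(qtls=[sg.QTLSpec(1, 1, 0.3, 1.0, 0.95)], structure_pve=0.10)


# ----------------------------------------------------------------------
# Phenotype simulation
# ----------------------------------------------------------------------

def test_phenotypes_deterministic_per_replicate(panel230):
    K = sg.compute_kinship(panel230)
    pcs = sg.compute_pca(panel230, k=5)
    d = sg.benchmark_design(n_reps=4, seed=5)
    a = sg.simulate_phenotypes(panel230, d, K, pcs)
    b = sg.simulate_phenotypes(panel230, d, K, pcs)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.phenotype, rb.phenotype)


def test_variance_accounting_on_large_panel():
    """Component variances add up to Var(y): within 1% when the components
    are mutually near-orthogonal (no structure term), and within 2.5% for
    the full design, where the structure and polygenic terms share the top
    PC directions and their cross-covariance dominates the sampling noise."""
    panel = sg.simulate_genotype_panel(
        n=1000, m=400, n_subpops=3, seed=3,
        required_positions=QTL_POSITIONS, required_mafs=QTL_MAFS,
    )
    K = sg.compute_kinship(panel)
    pcs = sg.compute_pca(panel, k=5)
    for structure_pve, n_reps, tol in ((0.0, 20, 0.01), (0.10, 50, 0.025)):
        design = sg.SimulationDesign(qtls=list(sg.BENCHMARK_QTLS),
                                     structure_pve=structure_pve,
                                     n_reps=n_reps, seed=21)
        cal = calibrate_qtl_effects(panel, design)
        recs = sg.simulate_phenotypes(panel, design, K, pcs)
        qtl_var = (panel.dosage[:, cal.qtl_idx] @ cal.effects).var()
        expected = (qtl_var + cal.structure_var + design.polygenic_var
                    * np.trace(K.values) / panel.n_lines + design.residual_var)
        mean_vy = np.mean([r.phenotype.var() for r in recs])
        assert abs(mean_vy - expected) / expected < tol


def test_no_genetics_gives_pure_noise(panel230):
    """With zero polygenic variance and no QTL or structure, the phenotype
    is independent noise, uncorrelated with the PCs."""
    K = sg.compute_kinship(panel230)
    pcs = sg.compute_pca(panel230, k=5)
    design = sg.SimulationDesign(qtls=[], polygenic_var=0.0, residual_var=1.0,
                                 structure_pve=0.0, n_reps=20, seed=2)
    recs = sg.simulate_phenotypes(panel230, design, K, pcs)
    mean_vy = np.mean([r.phenotype.var() for r in recs])
    assert abs(mean_vy - 1.0) < 0.15
    cors = []
    S = pcs.scores
    for rec in recs:
        y = rec.phenotype
        for k in range(S.shape[1]):
            cors.append(np.corrcoef(y, S[:, k])[0, 1])
    assert abs(np.mean(cors)) < 0.05 and np.mean(np.abs(cors)) < 0.12


def test_null_design_variance_additivity(panel230):
    """All QTL effects zero and no structure: Var(y) ~ sg^2 mean(diag K) + se^2."""
    K = sg.compute_kinship(panel230)
    pcs = sg.compute_pca(panel230, k=5)
    qtls = [sg.QTLSpec(c, p, m, 1.0, 0.0) for (c, p), m in zip(QTL_POSITIONS, QTL_MAFS)]
    design = sg.SimulationDesign(qtls=qtls, structure_pve=0.0, n_reps=30, seed=8)
    recs = sg.simulate_phenotypes(panel230, design, K, pcs)
    expected = np.diag(K.values).mean() + 1.0
    mean_vy = np.mean([r.phenotype.var() for r in recs])
    assert abs(mean_vy - expected) / expected < 0.10


def test_structure_pcs_exceeding_available_errors(panel230):
    K = sg.compute_kinship(panel230)
    pcs = sg.compute_pca(panel230, k=3)
    design = sg.benchmark_design(n_reps=1)  # wants 5 structure PCs
    with pytest.raises(ValueError):
        sg.simulate_phenotypes(panel230, design, K, pcs)


# ----------------------------------------------------------------------
# Multi-trait fixture generator
# ----------------------------------------------------------------------

def test_trait_panel_h2_one_replicates_identical(small_panel):
    tab = sg.simulate_trait_panel(small_panel, n_traits=2, h2=1.0,
                                  n_reps_per_line=3, seed=0)
    wide = tab.pivot_table(index="line_id", columns="rep_id", values="trait1")
    assert np.allclose(wide.iloc[:, 0], wide.iloc[:, 1])
    assert np.allclose(wide.iloc[:, 0], wide.iloc[:, 2])


def test_trait_panel_identity_corr_gives_independent_traits(panel230):
    tab = sg.simulate_trait_panel(panel230, n_traits=7, h2=0.6,
                                  trait_corr=np.eye(7), n_reps_per_line=3, seed=1)
    means = tab.groupby("line_id")[[f"trait{i+1}" for i in range(7)]].mean()
    r = np.corrcoef(means.to_numpy().T)
    off = r[~np.eye(7, dtype=bool)]
    assert np.mean(np.abs(off)) < 0.1


def test_trait_panel_rejects_non_psd_corr(small_panel):
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])
    with pytest.raises(ValueError):
        sg.simulate_trait_panel(small_panel, n_traits=2, trait_corr=bad)


def test_design_yaml_roundtrip(tmp_path):
    d = sg.benchmark_design(n_reps=17, seed=99)
    path = tmp_path / "design.yaml"
    design_to_yaml(d, path)
    back = design_from_yaml(path)
    assert back == d
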