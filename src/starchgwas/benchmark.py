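"""Monte-Carlo power / Type-I-error benchmark of the four GWAS engines.

For each simulated replicate the phenotype is drawn from the benchmark
variance-component design, every requested engine is run with its native
significance rule (p < 1/m for the single-locus mixed model and the
iterative pseudo-QTN engine; LOD > 3 for the EM-empirical-Bayes and L1
engines), and detections are matched to the simulated QTL within a 1-kb
window.  Power for a QTL is the fraction of replicates with a matched
significant detection; the Type I error of an engine is the pooled ratio
of false positives over all marker-tests at markers carrying no simulated
effect (the per-replicate mean is also reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mlm_single import fit_null_mlm, scan_single_locus
from .multilocus import scan_farmcpu, scan_fastmremma, scan_lasso
from .panel import GenotypePanel
from .popgen import KinshipMatrix, PCResult, compute_kinship, compute_pca
from .simdata import SimulationDesign, TruthRecord, simulate_phenotypes

log = logging.getLogger(__name__)

__all__ = ["METHODS", "match_detections", "run_power_study", "PowerStudyResult"]

METHODS = ("single_mlm", "fastmremma", "farmcpu", "lasso")

#: native significance rule per engine
THRESHOLD_RULES = {
    "single_mlm": "p < 1/m",
    "farmcpu": "p < 1/m",
    "fastmremma": "LOD > 3",
    "lasso": "LOD > 3",
}


def match_detections(detections, truth: TruthRecord, window: int = 1000):
    """Match significant detections to simulated QTL within ``window`` bp.

    A detection matches QTL q iff it lies on the same chromosome within
    ``window`` bp (inclusive); each detection is assigned to at most one
    QTL — the nearest, with the lower QTL position breaking distance ties.
    Several detections inside one QTL's window all count toward that single
    hit (none become false positives); unmatched detections are false
    positives.

    ``detections`` may be a result DataFrame (rows with ``chrom``/``pos``;
    only rows flagged ``significant`` are used if that column is present)
    or a sequence of (chrom, pos) pairs.  Returns ``(hits, n_fp)`` with
    ``hits`` a boolean array aligned to ``truth.qtl_positions``.
    """
    if isinstance(detections, pd.DataFrame):
        df = detections
        if "significant" in df.columns:
            df = df[df["significant"]]
        pairs = list(zip(df["chrom"].astype(int), df["pos"].astype(int)))
    else:
        pairs = [(int(c), int(p)) for c, p in detections]
    qtls = truth.qtl_positions
    hits = np.zeros(len(qtls), dtype=bool)
    n_fp = 0
    for c, p in pairs:
        best_q, best_d = -1, None
        for qi, (qc, qp) in enumerate(qtls):
            if qc != c:
                continue
            dist = abs(p - qp)
            if dist <= window and (best_d is None or dist < best_d
                                   or (dist == best_d and qp < qtls[best_q][1])):
                best_q, best_d = qi, dist
        if best_q >= 0:
            hits[best_q] = True
        else:
            n_fp += 1
    return hits, n_fp


@dataclass
class PowerStudyResult:
    power: pd.DataFrame                  # QTL x method, fractions in [0, 1]
    type_i_error: pd.Series              # pooled FP ratio per method
    type_i_error_rep_mean: pd.Series     # mean over replicates of per-rep ratio
    n_reps: int
    n_markers: int
    thresholds: dict
    detections: pd.DataFrame             # per-replicate detection log

    def to_table(self) -> pd.DataFrame:
        """Benchmark table: power (%) per QTL plus a Type I error row."""
        tab = (self.power * 100).copy()
        tab.loc["Type I error"] = self.type_i_error
        return tab


def run_power_study(
    panel: GenotypePanel,
    design: SimulationDesign,
    methods=METHODS,
    n_reps: int = 100,
    seed: int = 0,
    n_pcs: int = 5,
    window: int = 1000,
    kinship: KinshipMatrix | None = None,
    pcs: PCResult | None = None,
) -> PowerStudyResult:
    """Run the Monte-Carlo benchmark over a subset of the four engines.

    The panel, kinship and PC scores are fixed across replicates; phenotype
    replicate r derives its seed from (``seed``, r) so the study is
    reproducible and resumable per replicate.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if kinship is None:
        kinship = compute_kinship(panel)
    if pcs is None:
        pcs = compute_pca(panel, k=max(n_pcs, design.structure_pcs))
    X = np.column_stack([np.ones(panel.n_lines), pcs.scores[:, :n_pcs]])
    m = panel.n_markers
    design = SimulationDesign(
        qtls=design.qtls, polygenic_var=design.polygenic_var,
        residual_var=design.residual_var, structure_pcs=design.structure_pcs,
        structure_pve=design.structure_pve, n_reps=n_reps, seed=seed,
        effect_mode=design.effect_mode,
    )
    truths = simulate_phenotypes(panel, design, kinship, pcs)
    n_qtl = len(design.qtls)
    hit_counts = {meth: np.zeros(n_qtl) for meth in methods}
    fp_counts = {meth: np.zeros(n_reps) for meth in methods}
    log_rows = []

    for r, truth in enumerate(truths):
        y = truth.phenotype
        for meth in methods:
            if meth == "single_mlm":
                res = scan_single_locus(y, X, kinship, panel)
            elif meth == "fastmremma":
                res = scan_fastmremma(y, X, kinship, panel)
            elif meth == "farmcpu":
                res = scan_farmcpu(y, X, panel)
            else:
                res = scan_lasso(y, X, panel, seed=seed + r)
            sig = res[res["significant"]]
            hits, n_fp = match_detections(sig, truth, window=window)
            hit_counts[meth] += hits
            fp_counts[meth][r] = n_fp
            for _, row in sig.iterrows():
                log_rows.append({
                    "replicate": r, "method": meth, "chrom": row["chrom"],
                    "pos": row["pos"], "p_value": row["p_value"], "lod": row["lod"],
                })
        if (r + 1) % 10 == 0:
            log.info("benchmark replicate %d/%d done", r + 1, n_reps)

    qtl_names = [f"QTL{i + 1}" for i in range(n_qtl)]
    power = pd.DataFrame(
        {meth: hit_counts[meth] / n_reps for meth in methods}, index=qtl_names
    )
    denom = n_reps * (m - n_qtl)
    pooled = pd.Series({meth: fp_counts[meth].sum() / denom for meth in methods})
    rep_mean = pd.Series({meth: (fp_counts[meth] / (m - n_qtl)).mean() for meth in methods})
    detections = pd.DataFrame(
        log_rows, columns=["replicate", "method", "chrom", "pos", "p_value", "lod"]
    )
    return PowerStudyResult(
        power=power,
        type_i_error=pooled,
        type_i_error_rep_mean=rep_mean,
        n_reps=n_reps,
        n_markers=m,
        thresholds={meth: THRESHOLD_RULES[meth] for meth in methods},
        detections=detections,
    )
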