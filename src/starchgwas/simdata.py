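"""Synthetic inbred association panels and simulated phenotypes.

The generator emulates a diverse inbred panel of the kind used for maize
association mapping: a handful of subpopulations (visible in PC space),
minor-allele frequencies bounded away from zero, and linkage disequilibrium
that decays with physical distance.  Phenotypes are drawn from the
variance-component model

    y = sum_j x_j a_j  +  Q gamma  +  g  +  e

with QTL dosages x_j, population-structure scores Q (leading principal
components of the panel itself), a polygenic effect g ~ N(0, sigma_g^2 K)
and residual e ~ N(0, sigma_e^2 I).  The default benchmark design places
eight QTL on the first eight chromosomes that jointly explain 56% of the
phenotypic variance, with polygenic and residual variances of one and a
five-PC structure term at 10% of the phenotypic variance.

LD dialect
----------
Within segments that share a base allele frequency, alleles are generated
by a Markov copy-chain along the chromosome: the allele at a marker copies
the previous marker's allele with probability c(d) = 0.1^(d / (2 L)) for
inter-marker distance d and block length L (``ld_block_len``), otherwise it
is drawn fresh.  The chain makes the expected dosage correlation between
two markers at distance d exactly c(d)^2 = 0.1^(d/L), i.e. mean r^2 crosses
0.1 at d = L by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .panel import GenotypePanel

__all__ = [
    "QTLSpec",
    "SimulationDesign",
    "TruthRecord",
    "CalibratedEffects",
    "MAIZE_CHROM_LENGTHS",
    "BENCHMARK_QTLS",
    "benchmark_design",
    "simulate_genotype_panel",
    "calibrate_qtl_effects",
    "simulate_phenotypes",
    "simulate_trait_panel",
    "design_to_yaml",
    "design_from_yaml",
]

#: Approximate B73 chromosome lengths (bp) for the ten maize chromosomes.
MAIZE_CHROM_LENGTHS: dict[int, int] = {
    1: 307_041_717,
    2: 244_442_276,
    3: 235_667_834,
    4: 246_994_605,
    5: 223_902_240,
    6: 174_033_170,
    7: 182_381_542,
    8: 181_122_637,
    9: 159_769_782,
    10: 150_982_314,
}

_NUCS = np.array(list("ACGT"))


@dataclass
class QTLSpec:
    """One simulated causal locus.

    ``effect`` is the additive allele-substitution effect in trait units per
    coded-allele copy; ``target_pve`` the fraction of phenotypic variance the
    locus should explain.
    """

    chrom: int
    pos: int
    maf: float
    effect: float
    target_pve: float

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"QTL maf must be in (0, 0.5], got {self.maf}")
        if not (0.0 <= self.target_pve <= 1.0):
            raise ValueError("target_pve must be in [0, 1]")


#: The eight-QTL benchmark design used throughout the power study:
#: chromosome, position (bp), MAF, additive effect, per-QTL variance fraction.
BENCHMARK_QTLS: list[QTLSpec] = [
    QTLSpec(1, 14_898_058, 0.335, 0.569, 0.04),
    QTLSpec(2, 19_326_559, 0.160, 0.842, 0.04),
    QTLSpec(3, 20_532_172, 0.307, 1.041, 0.06),
    QTLSpec(4, 13_181_343, 0.452, 0.667, 0.06),
    QTLSpec(5, 15_819_352, 0.204, 0.935, 0.08),
    QTLSpec(6, 27_154_881, 0.378, 0.766, 0.08),
    QTLSpec(7, 16_672_999, 0.085, 1.564, 0.10),
    QTLSpec(8, 22_685_122, 0.217, 1.028, 0.10),
]


@dataclass
class SimulationDesign:
    """Variance-component design for the phenotype simulator."""

    qtls: list[QTLSpec]
    polygenic_var: float = 1.0
    residual_var: float = 1.0
    structure_pcs: int = 5
    structure_pve: float = 0.10
    n_reps: int = 200
    seed: int = 0
    effect_mode: str = "matched_pve"  # or "printed_effects"

    def __post_init__(self) -> None:
        if not (0.0 <= self.structure_pve < 1.0):
            raise ValueError("structure_pve must be in [0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.effect_mode not in ("matched_pve", "printed_effects"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")
        total = sum(q.target_pve for q in self.qtls) + self.structure_pve
        if total >= 1.0:
            raise ValueError(
                f"QTL target PVE plus structure PVE is {total:.3f}; must be < 1"
            )

    @property
    def total_qtl_pve(self) -> float:
        return float(sum(q.target_pve for q in self.qtls))


def benchmark_design(
    n_reps: int = 200, seed: int = 0, effect_mode: str = "matched_pve"
) -> SimulationDesign:
    """The standard eight-QTL benchmark design (56% total QTL PVE)."""
    return SimulationDesign(
        qtls=list(BENCHMARK_QTLS),
        polygenic_var=1.0,
        residual_var=1.0,
        structure_pcs=5,
        structure_pve=0.10,
        n_reps=n_reps,
        seed=seed,
        effect_mode=effect_mode,
    )


@dataclass
class TruthRecord:
    """Realized truth of one simulation replicate."""

    replicate: int
    qtl_positions: list[tuple[int, int]]
    effects: np.ndarray
    realized_pve: np.ndarray
    total_qtl_pve: float
    phenotype: np.ndarray


@dataclass
class CalibratedEffects:
    """Effects and variance budget implied by a design on a concrete panel."""

    effects: np.ndarray          # allele-substitution effect per QTL
    qtl_idx: np.ndarray          # marker index of each QTL in the panel
    qtl_var: np.ndarray          # per-QTL variance contribution a^2 Var(x)
    structure_var: float         # variance of the structure term Q gamma
    total_var: float             # implied total phenotypic variance


# ======================================================================
# Genotype panel generation
# ======================================================================

def _allocate_markers(m: int, lengths: dict[int, int]) -> dict[int, int]:
    """Largest-remainder apportionment of m markers across chromosomes."""
    chroms = sorted(lengths)
    total = sum(lengths.values())
    raw = {c: m * lengths[c] / total for c in chroms}
    counts = {c: int(raw[c]) for c in chroms}
    short = m - sum(counts.values())
    for c in sorted(chroms, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _draw_required(rng, n: int, maf: float, maf_lo: float) -> np.ndarray:
    """Allele indicators at a target MAF, resampled until the realized MAF is
    within 0.045 of the target and not below the panel floor."""
    for _ in range(500):
        a = (rng.random(n) < maf).astype(np.float64)
        p = a.mean()
        realized = min(p, 1 - p)
        if abs(realized - maf) <= 0.045 and realized >= min(maf_lo, maf):
            return a
    raise RuntimeError(f"could not realize MAF {maf} on {n} lines")


def simulate_genotype_panel(
    n: int = 230,
    m: int = 5000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_subpops: int = 3,
    ld_block_len: int = 250_000,
    chrom_lengths: dict[int, int] | None = None,
    required_positions: list[tuple[int, int]] | None = None,
    required_mafs: list[float] | None = None,
    fst: float = 0.15,
    seed: int = 0,
) -> GenotypePanel:
    """Generate a synthetic inbred panel with structure and decaying LD.

    Parameters
    ----------
    n, m : panel dimensions (lines x markers).
    maf_range : (lo, hi) bounds for base minor-allele frequencies; every
        marker's realized MAF is at least ``lo`` after generation.
    n_subpops : number of subpopulations; subgroup allele frequencies are
        drawn from a Balding-Nichols model with differentiation ``fst``.
    ld_block_len : distance (bp) at which expected pairwise r^2 has decayed
        to 0.1 (see module docstring for the copy-chain construction).
    chrom_lengths : mapping chromosome -> length (bp); defaults to the ten
        maize chromosomes.
    required_positions : (chrom, pos) pairs that must appear as markers,
        e.g. benchmark QTL; drawn independently of structure and LD chains.
    required_mafs : target MAF per required position (default: drawn from
        ``maf_range``); realized MAF lands within 0.045 of the target.
    """
    rng = np.random.default_rng(seed)
    lengths = dict(chrom_lengths or MAIZE_CHROM_LENGTHS)
    required_positions = list(required_positions or [])
    lo, hi = maf_range
    if not (0.0 < lo < hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo < hi <= 0.5, got {maf_range}")
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 lines and m >= 1 markers")
    if n_subpops < 1 or n_subpops > n:
        raise ValueError("n_subpops must be in [1, n]")
    if len(required_positions) > m:
        raise ValueError("more required positions than markers")
    for c, p in required_positions:
        if c not in lengths or not (1 <= p <= lengths[c]):
            raise ValueError(f"required position ({c}, {p}) outside chromosome bounds")
    if required_mafs is None:
        required_mafs = [float(rng.uniform(max(lo, 0.1), hi)) for _ in required_positions]
    elif len(required_mafs) != len(required_positions):
        raise ValueError("required_mafs must align with required_positions")

    # --- marker map -----------------------------------------------------
    req_by_chrom: dict[int, list[tuple[int, float]]] = {}
    for (c, p), f in zip(required_positions, required_mafs):
        req_by_chrom.setdefault(c, []).append((p, f))
    counts = _allocate_markers(m - len(required_positions), lengths)
    chrom_arr, pos_arr, req_maf_arr = [], [], []
    required_mask = []
    for c in sorted(lengths):
        taken = {p for p, _ in req_by_chrom.get(c, [])}
        k = counts.get(c, 0)
        ps: set[int] = set()
        while len(ps) < k:
            cand = rng.integers(1, lengths[c] + 1, size=k - len(ps))
            ps.update(int(x) for x in cand if int(x) not in taken)
        entries = [(p, False, np.nan) for p in ps] + [
            (p, True, f) for p, f in req_by_chrom.get(c, [])
        ]
        entries.sort(key=lambda t: t[0])
        for p, is_req, f in entries:
            chrom_arr.append(c)
            pos_arr.append(p)
            required_mask.append(is_req)
            req_maf_arr.append(f)
    chrom = np.array(chrom_arr, dtype=np.int64)
    pos = np.array(pos_arr, dtype=np.int64)
    required_mask = np.array(required_mask, dtype=bool)
    req_maf_arr = np.array(req_maf_arr, dtype=float)

    # --- subpopulations and segment frequencies ------------------------
    subpop = (np.arange(n) * n_subpops) // n  # balanced, deterministic
    seg_len = 10 * ld_block_len
    seg_id = np.stack([chrom, pos // seg_len])
    decay = math.log(10.0) / (2.0 * ld_block_len)  # copy prob exp(-decay * d)

    dosage = np.empty((n, m), dtype=np.float64)
    prev_allele: np.ndarray | None = None
    prev_key: tuple[int, int] | None = None
    prev_pos = -1
    freqs = np.empty(n_subpops)
    for j in range(m):
        if required_mask[j]:
            dosage[:, j] = 2.0 * _draw_required(rng, n, req_maf_arr[j], lo)
            continue
        key = (int(seg_id[0, j]), int(seg_id[1, j]))
        if key != prev_key:
            # new shared-frequency segment: Balding-Nichols subgroup freqs
            p0 = rng.uniform(lo, hi)
            if rng.random() < 0.5:
                p0 = 1.0 - p0
            if fst > 0 and n_subpops > 1:
                a, b = p0 * (1 - fst) / fst, (1 - p0) * (1 - fst) / fst
                freqs = np.clip(rng.beta(a, b, size=n_subpops), 0.01, 0.99)
            else:
                freqs[:] = p0
            prev_allele = None
        pline = freqs[subpop]
        fresh = (rng.random(n) < pline).astype(np.float64)
        if prev_allele is None:
            allele = fresh
        else:
            c = math.exp(-decay * (pos[j] - prev_pos))
            copy = rng.random(n) < c
            allele = np.where(copy, prev_allele, fresh)
        dosage[:, j] = 2.0 * allele
        prev_allele = allele
        prev_key = key
        prev_pos = pos[j]

    # --- enforce the MAF floor ------------------------------------------
    p_alt = dosage.mean(axis=0) / 2.0
    maf = np.minimum(p_alt, 1 - p_alt)
    for j in np.flatnonzero(maf < lo):
        if required_mask[j]:
            continue  # required markers already honor their own targets
        target = max(min(2 * lo, 0.5), lo * 1.5)
        for _ in range(200):
            col = (rng.random(n) < target).astype(np.float64) * 2.0
            pj = col.mean() / 2.0
            if min(pj, 1 - pj) >= lo:
                dosage[:, j] = col
                break
        else:  # pragma: no cover - effectively unreachable
            raise RuntimeError("failed to enforce MAF floor")

    pairs = rng.integers(0, 4, size=m)
    ref = _NUCS[pairs]
    alt = _NUCS[(pairs + 1 + rng.integers(0, 3, size=m)) % 4]
    line_ids = [f"L{i + 1:03d}" for i in range(n)]
    return GenotypePanel(line_ids, chrom, pos, ref, alt, dosage)


# ======================================================================
# Phenotype simulation
# ======================================================================

def calibrate_qtl_effects(panel: GenotypePanel, design: SimulationDesign) -> CalibratedEffects:
    """Resolve a design's variance budget on a concrete panel.

    In ``matched_pve`` mode the total phenotypic variance T solves

        (sigma_g^2 + sigma_e^2) / T = 1 - sum(target_pve) - structure_pve

    and each QTL effect is rescaled so a_j^2 Var(x_j) = target_pve_j * T.
    In ``printed_effects`` mode the design effects are used verbatim and T
    follows from summing the realized component variances.  The structure
    term's variance is structure_pve * T in both modes.
    """
    qtl_idx = np.array(
        [panel.marker_index(q.chrom, q.pos) for q in design.qtls], dtype=int
    )
    x = panel.dosage[:, qtl_idx]
    if np.isnan(x).any():
        raise ValueError("QTL markers must be complete (impute first)")
    var_x = x.var(axis=0)
    base = design.polygenic_var + design.residual_var

    if design.effect_mode == "matched_pve":
        free = 1.0 - design.total_qtl_pve - design.structure_pve
        if free <= 0:
            raise ValueError("target PVEs infeasible: sum >= 1 - structure_pve")
        total_var = base / free
        targets = np.array([q.target_pve for q in design.qtls])
        signs = np.array([math.copysign(1.0, q.effect) if q.effect else 1.0 for q in design.qtls])
        with np.errstate(divide="ignore", invalid="ignore"):
            effects = signs * np.sqrt(np.where(var_x > 0, targets * total_var / var_x, 0.0))
        effects[targets == 0] = 0.0
        qtl_var = targets * total_var
    else:
        effects = np.array([q.effect for q in design.qtls], dtype=float)
        qtl_var = effects**2 * var_x
        denom = 1.0 - design.structure_pve
        total_var = (qtl_var.sum() + base) / denom

    structure_var = design.structure_pve * total_var
    return CalibratedEffects(effects, qtl_idx, qtl_var, structure_var, total_var)


def simulate_phenotypes(panel: GenotypePanel, design: SimulationDesign, kinship, pcs) -> list[TruthRecord]:
    """Draw ``design.n_reps`` phenotype replicates under the full model.

    ``kinship`` and ``pcs`` are the :class:`~starchgwas.popgen.KinshipMatrix`
    and :class:`~starchgwas.popgen.PCResult` computed from ``panel``.  The
    polygenic effect is g ~ N(0, sigma_g^2 K); the structure term uses the
    first ``structure_pcs`` PC scores with a random coefficient vector drawn
    per replicate and rescaled so the term's sample variance equals its
    budgeted share.  Replicate r uses a seed derived deterministically from
    (design.seed, r), so any replicate can be regenerated in isolation.
    """
    n = panel.n_lines
    calib = calibrate_qtl_effects(panel, design)
    qtl_term = panel.dosage[:, calib.qtl_idx] @ calib.effects
    K = kinship.values if hasattr(kinship, "values") else np.asarray(kinship)
    d, U = np.linalg.eigh(K)
    if d.min() < -1e-8:
        raise ValueError("kinship matrix is not positive semi-definite")
    d = np.clip(d, 0.0, None)
    scores = pcs.scores if hasattr(pcs, "scores") else np.asarray(pcs)
    if design.structure_pve > 0 and design.structure_pcs > scores.shape[1]:
        raise ValueError(
            f"structure_pcs={design.structure_pcs} exceeds available PCs "
            f"({scores.shape[1]})"
        )
    Q = scores[:, : design.structure_pcs]

    records: list[TruthRecord] = []
    positions = [(q.chrom, q.pos) for q in design.qtls]
    per_qtl_num = calib.effects**2 * panel.dosage[:, calib.qtl_idx].var(axis=0)
    for r in range(design.n_reps):
        rng = np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=(r,)))
        g = U @ (rng.standard_normal(n) * np.sqrt(design.polygenic_var * d))
        e = rng.standard_normal(n) * math.sqrt(design.residual_var)
        y = qtl_term + g + e
        if design.structure_pve > 0:
            s = Q @ rng.standard_normal(Q.shape[1])
            sv = s.var()
            if sv > 0:
                y = y + s * math.sqrt(calib.structure_var / sv)
        vy = y.var()
        realized = per_qtl_num / vy
        records.append(
            TruthRecord(
                replicate=r,
                qtl_positions=positions,
                effects=calib.effects.copy(),
                realized_pve=realized,
                # the design's total (e.g. 56%) is the sum of per-QTL shares,
                # so the realized total follows the same convention
                total_qtl_pve=float(realized.sum()),
                phenotype=y,
            )
        )
    return records


def simulate_trait_panel(
    panel: GenotypePanel,
    n_traits: int = 7,
    h2=0.6,
    trait_corr: np.ndarray | None = None,
    n_reps_per_line: int = 3,
    seed: int = 0,
    trait_names: list[str] | None = None,
):
    """Replicate-level multi-trait phenotypes for the heritability stage.

    Line (genetic) and residual variances are in ratio h2 / (1 - h2) per
    trait, with total variance 1; the same correlation structure is applied
    to the genetic and residual draws so the trait correlation matrix equals
    ``trait_corr``.  Returns a long-format DataFrame (line_id, rep_id,
    trait columns), emulating a replicated randomized-block trait table.
    """
    import pandas as pd

    n = panel.n_lines
    h2 = np.broadcast_to(np.asarray(h2, dtype=float), (n_traits,)).copy()
    if ((h2 < 0) | (h2 > 1)).any():
        raise ValueError("h2 entries must be in [0, 1]")
    if trait_corr is None:
        trait_corr = np.eye(n_traits)
    trait_corr = np.asarray(trait_corr, dtype=float)
    if trait_corr.shape != (n_traits, n_traits) or not np.allclose(trait_corr, trait_corr.T):
        raise ValueError("trait_corr must be a symmetric n_traits x n_traits matrix")
    evals = np.linalg.eigvalsh(trait_corr)
    if evals.min() < -1e-8:
        raise ValueError("trait_corr is not positive semi-definite")
    L = np.linalg.cholesky(trait_corr + 1e-10 * np.eye(n_traits))
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n, n_traits)) @ L.T * np.sqrt(h2)
    names = trait_names or [f"trait{t + 1}" for t in range(n_traits)]
    rows = []
    for rep in range(n_reps_per_line):
        e = rng.standard_normal((n, n_traits)) @ L.T * np.sqrt(1.0 - h2)
        block = pd.DataFrame(u + e, columns=names)
        block.insert(0, "rep_id", rep + 1)
        block.insert(0, "line_id", panel.line_ids)
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


# ======================================================================
# Design config and truth I/O
# ======================================================================

def design_to_yaml(design: SimulationDesign, path) -> None:
    doc = {
        "qtls": [
            {"chrom": q.chrom, "pos": q.pos, "maf": q.maf,
             "effect": q.effect, "target_pve": q.target_pve}
            for q in design.qtls
        ],
        "polygenic_var": design.polygenic_var,
        "residual_var": design.residual_var,
        "structure_pcs": design.structure_pcs,
        "structure_pve": design.structure_pve,
        "n_reps": design.n_reps,
        "seed": design.seed,
        "effect_mode": design.effect_mode,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def design_from_yaml(path) -> SimulationDesign:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    qtls = [QTLSpec(**q) for q in doc.pop("qtls")]
    return SimulationDesign(qtls=qtls, **doc)


def truth_to_frame(records: list[TruthRecord]):
    """Flatten truth records to a TSV-ready frame (one row per replicate x QTL)."""
    import pandas as pd

    rows = []
    for rec in records:
        for (c, p), a, v in zip(rec.qtl_positions, rec.effects, rec.realized_pve):
            rows.append(
                {"replicate": rec.replicate, "chrom": c, "pos": p,
                 "effect": a, "realized_pve": v}
            )
    return pd.DataFrame(rows)
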