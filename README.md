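# starchgwas

Single- and multi-locus genome-wide association tools for inbred association
panels, built around the study design used to map maize starch pasting
properties (peak/trough/final/breakdown/setback viscosity, pasting time and
pasting temperature measured by Rapid Visco Analyser on a 230-line panel).

The package is for quantitative geneticists who want to (i) run and compare
four GWAS engines on an inbred panel, (ii) estimate heritability and
population structure for the traits being mapped, and (iii) quantify each
engine's statistical power and Type I error by Monte-Carlo simulation on a
synthetic panel whose structure mirrors the real one.

## What it computes

**Phenotype model.** Phenotypes follow the variance-component model

```
y = Σ_j x_j a_j + Q γ + g + e,   g ~ N(0, σ²_g K),   e ~ N(0, σ²_e I)
```

with `x_j` the allele dosage (0/2 on inbreds) of QTL *j* with additive
effect `a_j`, `Q` the leading principal-component scores of the genotype
matrix (population structure), `K` the standardized genomic relationship
matrix, and heritability reported as `h² = σ²_g / (σ²_g + σ²_e)` from a
one-way REML fit of replicated trait records.

**Four association engines**, all sharing one result schema:

| engine | model | significance rule |
|---|---|---|
| `scan_single_locus` | exact single-locus mixed model (per-marker REML re-optimization of δ = σ²_e/σ²_g after one eigendecomposition of K) | p < 1/m |
| `scan_fastmremma` | two-stage multi-locus: random-effect screen on polygenic-whitened data, then joint EM empirical-Bayes fit of the retained markers | LOD > 3 |
| `scan_farmcpu` | iterative fixed-effect scan with pseudo-QTN covariates, pseudo-QTN set chosen by a binned random-effect model | p < 1/m |
| `scan_lasso` | L1-penalized multi-marker regression (penalty by cross-validation) with a ridge-curvature Wald test on the active set | LOD > 3 |

LOD and p are bridged by the 1-df chi-square convention
`lod = qchisq(1−p, 1) / (2 ln 10)`, so LOD 3 ≈ p 2.0e-4.

**Benchmark.** `run_power_study` simulates phenotypes from an eight-QTL
design (jointly 56% of phenotypic variance; polygenic and residual variance
1; five-PC structure term at 10%), runs each engine with its native
threshold, matches detections to the simulated QTL within 1 kb, and reports
per-QTL power plus the pooled Type I error over markers carrying no effect.

Supporting stages: VCF/TSV genotype I/O with MAF > 2% / missing < 20%
filters and mean imputation, VanRaden kinship, PCA structure control,
binned LD-decay curves with an r² cutoff crossing distance, Pearson trait
correlations with significance flags, QTN calling across methods
(pleiotropy and sign-consistency summaries), and candidate-gene windows
(±250 kb) from a GFF3.

## Worked example

`examples/power_benchmark.py` runs a reduced benchmark (1,000 markers, 10
replicates, two engines):

```
power (%) per simulated QTL and pooled Type I error:
              single_mlm  fastmremma
QTL1              0.0000        20.0
QTL2              0.0000         0.0
QTL3             30.0000        50.0
QTL4             90.0000        90.0
QTL5             70.0000        90.0
QTL6            100.0000       100.0
QTL7            100.0000       100.0
QTL8            100.0000       100.0
Type I error      0.0005         0.0

average power (%):
single_mlm    61.3
fastmremma    68.8
```

Large-effect loci (QTL7/QTL8, 10% of variance each) are detected every
time; the 4% loci (QTL1/QTL2) are mostly missed at this scale; the
multi-locus engine is more powerful on average (68.8% vs 61.3%), and the
pooled Type I error of the LOD > 3 engine sits below the p < 1/m engine's.

The other examples cover heritability/correlations
(`heritability_and_correlations.py`), structure and LD decay
(`structure_and_ld.py`), a four-engine scan with QTN calling
(`simulate_and_scan.py`) and candidate-gene reporting (`qtn_report.py`).
A thin CLI mirrors the library: `starchgwas simulate-genotypes | filter |
kinship | pca | ld-decay | h2 | scan | benchmark | report`.

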