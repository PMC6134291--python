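# Methods

## Phenotype model

All simulation and inference in this package is organized around the
variance-component model for a quantitative trait measured on `n` inbred
lines genotyped at `m` biallelic markers:

```
y = Σ_j x_j a_j + Q γ + g + e,    g ~ N(0, σ²_g K),    e ~ N(0, σ²_e I)
```

* `x_j` — allele dosage of causal locus *j*. Inbred lines carry only the
  two homozygous states, coded **0/2** (dosage of the alt allele).  Under
  this coding a marker with coded-allele frequency `p` has variance
  `4p(1−p)`, and every effect size in the package is "trait units per
  coded-allele copy".  Heterozygotes never occur in the generator and are
  set missing (or rejected) on input.
* `Q` — scores of the leading principal components of the standardized
  genotype matrix; the structure term models subpopulation-level trait
  differences.
* `K` — standardized (VanRaden-type) genomic relationship `K = W W'/m`
  with `W` the column-standardized dosage matrix.  `trace(K) = n` exactly
  when no markers are dropped, so σ²_g is on the per-line variance scale.
* Narrow-sense heritability is reported as `h² = σ²_g/(σ²_g + σ²_e)` — the
  plain variance-component ratio, **not** the line-mean ratio
  `σ²_g/(σ²_g + σ²_e/r)`.  Only the former reproduces the printed
  heritabilities of the reference trait table from its printed variance
  components, so it is adopted as the package convention.

## Synthetic panel generator (`simdata`)

The generator emulates a diverse inbred association panel; it is first-class
tested code, not a fixture.

* **Structure.** Lines are split evenly into `n_subpops` subpopulations
  (default 3).  Subgroup allele frequencies follow a Balding–Nichols model
  around a shared base frequency with differentiation `fst` (default 0.15),
  which is ample for PC-space separation of the subgroups (the generator's
  own acceptance property: silhouette > 0.5 on PC1 for two subpopulations).
* **LD.** Chromosomes are divided into segments (10 × `ld_block_len`) that
  share a base frequency; within a segment, alleles follow a Markov
  copy-chain: the allele at each marker copies its left neighbor with
  probability `c(d) = 0.1^(d/(2L))` for distance `d` and block length `L`,
  else it is drawn fresh from the subgroup frequency.  This makes the
  expected dosage correlation between two markers at distance `d` exactly
  `c(d)²= 0.1^(d/L)`, i.e. the mean-r² curve crosses 0.1 at `d = L` by
  construction (default `L` = 250 kb, the decay scale reported for diverse
  maize panels).  A latent-Gaussian copula was rejected because threshold
  attenuation makes the crossing distance analytically uncontrollable.
* **Required (QTL) markers** are placed at exact coordinates, drawn
  independently of the subpopulation model and of the copy-chains, and
  rejection-sampled until the realized MAF is within 0.045 of the target.
  This keeps the QTL term near-orthogonal to structure and polygenic terms,
  which is what makes the variance budget below exact.
* **MAF floor.**  Markers falling below `maf_range[0]` after sampling are
  redrawn, so the panel behaves like a post-QC panel.

What the generator does **not** emulate: coalescent genealogies,
recombination maps, allele-frequency spectra of real GBS data, genotyping
error, and — importantly — the marker density of a 145k-SNP panel.  Desk
runs use m = 5,000, so each QTL's signal is carried by essentially one
marker instead of an LD cluster.  Consequences are discussed under
*Benchmark* below.

## Effect calibration and the variance budget

The benchmark design assigns eight QTL on chromosomes 1–8 with
per-QTL variance fractions (4, 4, 6, 6, 8, 8, 10, 10)% — 56% jointly —
polygenic and residual variances of 1, and a five-PC structure term at 10%
of phenotypic variance.

In the default `matched_pve` mode the total phenotypic variance `T` solves

```
(σ²_g + σ²_e) / T = 1 − Σ_j pve_j − pve_structure    ⇒    0.34 T = 2,  T ≈ 5.882
```

and each effect is set to `a_j = sqrt(pve_j · T / Var(x_j))` using the
realized marker variance, so the per-QTL variance contributions match the
design targets exactly by construction.  The realized *total* QTL share is
reported as the sum of per-QTL shares — the same arithmetic by which the
eight design fractions total 56% — and its across-replicate mean lands on
56% up to sampling noise in Var(y).  Part of that noise is panel-level: the
sample cross-covariances among the eight QTL markers are fixed once a panel
is drawn (standard deviation ≈ 3 points of the total on a 230-line panel),
so estimating the design expectation requires averaging over fresh panels,
not only over phenotype draws; the calibration checks therefore spread
their 50 replicates over 10 independently generated panels.  The alternative
`printed_effects` mode uses the design's literal effect sizes; it exists
for fidelity experiments because printed effects and printed variance
shares can only be simultaneously true on the original (unavailable)
genotype panel.  The structure coefficient vector γ is redrawn per
replicate and rescaled so the structure term's sample variance equals
`pve_structure · T` exactly.

Per-replicate seeds derive from `(design.seed, replicate)` via
`numpy.random.SeedSequence` spawn keys, so any replicate regenerates in
isolation.

## The four engines

**Single-locus exact mixed model.**  `K` is eigendecomposed once; on the
rotated data the covariance is `σ²_g diag(d + δ)` with `δ = σ²_e/σ²_g`.
The restricted likelihood profiles analytically over the fixed effects and
σ²_g and is maximized over δ alone.  The null fit uses a 100-point
log-grid on [1e-5, 1e5] plus bounded Brent refinement; the scan
re-optimizes δ **per marker** (no P3D/EMMAX approximation) with a shared
21-point grid followed by a per-marker quadratic refinement on the log
scale, kept only when it improves the criterion.  Inference is a two-sided
Wald t-test with `n − q − 1` degrees of freedom, which collapses exactly to
ordinary regression when `K = I`.  Constant markers report `p = 1`,
effect 0.

**Two-stage EM empirical Bayes.**  Stage 1 whitens `y`, the covariates and
all markers by `(σ̂²_g K + σ̂²_e I)^(-1/2)` from the null fit, moves to the
orthogonal complement of the covariates, and screens each marker with the
1-df test of its variance component (equivalent to the score test of
σ²_j = 0, i.e. the whitened regression t-test); markers at
p ≤ `stage1_alpha` (default 0.005, the "defaults" surrogate) are retained,
capped at min(n/2, 200) by best p as a safety valve.  Stage 2 fits the
retained markers jointly with per-marker normal priors, estimating the
prior variances and σ²_e by an EM loop (relative-change tolerance 1e-6,
1,000-iteration cap; non-convergence returns the best iterate with a flag).
Each marker's LOD is the likelihood ratio of zeroing its variance component
in the fitted covariance (fixing the others), divided by 2 ln 10.

**Iterative pseudo-QTN engine.**  Each iteration scans all markers in a
fixed-effect model with the structure covariates plus the current
pseudo-QTNs (a marker is never its own covariate; pseudo-QTN covariates in
LD r² > 0.7 with the tested marker are dropped for that test), then
re-selects pseudo-QTNs: markers with scan p ≤ 0.01 are binned by position
at bin sizes {0.5, 5, 50} Mb, the best marker per bin represents it, and
the candidate set (top 5/10/15 bins per size) maximizing the restricted
likelihood of a random-effect model whose relationship matrix is built from
the candidates is adopted.  Iteration stops when the set repeats
(oscillation stops at `max_iter` with a flag); per the method's published
default, no iteration starts unless some marker reaches 0.01/m on the first
scan, which keeps null phenotypes from accruing noise pseudo-QTNs.
Iteration 1 is by construction the plain GLM + PC scan.

**L1 with Wald significance.**  Covariates are projected out of the
phenotype and all markers; markers are standardized internally.  The L1
path and cross-validation (5 seeded folds, minimum mean squared prediction
error) run through scikit-learn's coordinate-descent solver — the canonical
implementation of the objective `(1/2n)‖y − Xβ‖² + λ‖β‖₁` — at a loose
tolerance, and the solution at the chosen λ is re-solved to high precision
(tol 1e-12), so KKT conditions hold to ~1e-6.  The significance recipe is
this package's declared stand-in (isolated in one function for
replacement): effect variances on the active set come from the
ridge-curvature sandwich
`σ̂²_e (X'X + λnI)⁻¹ X'X (X'X + λnI)⁻¹` with `σ̂²_e = RSS/(n − q − |A|)`,
feeding a Wald z → p → LOD test.  `λ = 0` falls back to ordinary least
squares (only valid for m < n).

**Thresholds.**  p < 1/m for the single-locus and pseudo-QTN engines;
LOD > 3 for the other two.  The global bridge
`lod = qchisq(1−p, 1)/(2 ln 10)` makes the two rules commensurable
(LOD 3 ⇔ p ≈ 2.0e-4); it is the package-wide convention for every LOD
column.

## Heritability, correlations, LD decay

* REML for the one-way model `y_ij = μ (+ block_j) + g_i + e_ij` reuses the
  same one-random-effect core (`K = ZZ'`), handling unbalanced tables; on
  balanced data it coincides with the ANOVA moment estimator whenever that
  is non-negative.  The F value is the one-way ANOVA ratio
  MS_line/MS_error.  The optional replicate (block) effect enters as a
  fixed term; the default is off because the reference analysis does not
  state whether blocks entered the REML model.
* Trait correlations are Pearson coefficients on line means with two-sided
  t-tests; zero-variance traits yield flagged NaNs rather than errors.
* LD decay bins squared Pearson correlations of dosages (composite LD —
  appropriate for unphased inbreds) by physical distance (default 5-kb bins
  to 1 Mb, same-chromosome pairs only); the decay distance is the first bin
  midpoint where a 3-bin rolling median falls below the cutoff, returning
  the maximum distance with a warning when the curve never crosses.

## Benchmark

Per replicate, each requested engine runs with its native threshold and
significant detections are matched to QTL within a 1-kb window (inclusive
at exactly 1,000 bp): each detection goes to its nearest in-window QTL
(lower position breaks ties), several detections inside one window collapse
to one hit and none count as false positives, and unmatched detections are
false positives.  Power(method, QTL) is the fraction of replicates with a
hit; Type I error is the pooled false-positive count over
`reps × (m − #QTL)` marker-tests (the per-replicate mean is also carried,
identical here because the marker count is constant).

**Problem sizes.**  The package's desk profile is a 230-line, 5,000-marker
panel and 100 replicates (about six minutes for all four engines on one
core); the calibration quantity uses 50 replicates.  The full-scale profile
(145,232 markers, 200 replicates) is supported by the same code path but is
a long-running job.

**What desk-scale results do and do not show.**  At m = 5,000 the 1/m
threshold is 2e-4 — 29× more lenient than at the full panel size — and the
sparse map leaves each QTL's signal on a single marker rather than an LD
cluster, so absolute powers run systematically higher than published
full-scale values and the pooled Type I error of a *calibrated* p < 1/m
engine is ~1/m ≈ 2e-4 by definition, not <1e-4.  What is preserved, and
what the acceptance checks lean on, are the calibration of the simulation
(56% total QTL PVE), the relative ordering (multi-locus engines out-power
the single-locus engine on average; the LOD > 3 engines hold far lower
Type I error), and the qualitative per-QTL structure (the same loci that
were hard for the single-locus engine at full scale are hard here).

## Numerical choices and degenerate inputs

* δ optimized on [1e-5, 1e5]; boundary solutions are honored (σ²_g ≈ 0
  reports δ at the upper bound and h² ≈ 0).  Negative kinship eigenvalues
  below −1e-8 are an error; small negatives are clipped to 0.
* Constant/collinear markers: p = 1 and zero effect in scans; excluded from
  standardization with a warning in kinship/PCA.
* QC thresholds are strict inequalities ("above 2%", "below 20%"); a marker
  failing both filters is counted in each tally but removed once.
* Missing dosages are mean-imputed per marker (one isolated operation so an
  alternative can be swapped in); an all-missing marker is an error naming
  the marker.
* Marker-effect PVE is reported as `effect² · Var(x)/Var(y)`, clipped to
  [0, 1]; the reference study never defines its per-QTN R², so this
  definition is declared rather than inferred.
* All stochastic steps (panel, phenotypes, CV folds, benchmark) take
  explicit seeds; identical seeds give bit-identical outputs.

## Known limitations

* The synthetic panel is a statistical stand-in, not a population-genetic
  simulation; absolute power/error numbers transfer to real panels only at
  the ordering/calibration level described above.
* The EM empirical-Bayes stage-1 screen and the L1 Wald recipe are declared
  surrogates for components whose original specifications live outside the
  reference study's text; both are isolated behind single functions.
* Binary traits, dominance, multi-environment variance decomposition and
  phased-haplotype LD are out of scope.
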