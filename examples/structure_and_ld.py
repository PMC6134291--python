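"""Population structure (kinship + PCA) and LD decay of a synthetic panel.

The generator plants three subpopulations and block LD that decays so mean
r^2 crosses 0.1 at the configured block length (250 kb here) — the scale a
maize association panel typically shows.
"""

import numpy as np

import starchgwas as sg

panel = sg.simulate_genotype_panel(
    n=230, m=2000, n_subpops=3, ld_block_len=250_000, seed=5,
    chrom_lengths={c: 60_000_000 for c in range(1, 11)},
)

kinship = sg.compute_kinship(panel)
print(f"kinship: trace {np.trace(kinship.values):.1f} over n={panel.n_lines} "
      "(standardized relationship, ~1 per line)")

pcs = sg.compute_pca(panel, k=8)
share = pcs.explained_var / panel.n_lines
print("top-PC variance shares:", np.round(share, 3))
print("  (a sharp drop after the leading components is the scree criterion "
      "for how many PCs to carry as structure covariates)")

table = sg.ld_decay(panel, max_dist=1_000_000, bin_width=25_000)
dist = sg.decay_distance(table, cutoff=0.1)
print(f"\nLD decay distance at r^2 = 0.1: {dist/1000:.0f} kb")
print(table.head(12).round(4).to_string(index=False))
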