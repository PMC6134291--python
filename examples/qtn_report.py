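"""QTN calling across methods and candidate-gene windows from a GFF3.

Builds two small association-result tables by hand, collapses them to QTN
calls, summarizes cross-method overlap (including the sign-consistency
check for co-identified loci), and annotates genes within +/- 250 kb.
"""

import tempfile

import pandas as pd

import starchgwas as sg
from starchgwas.mlm_single import RESULT_COLUMNS


def result(trait, method, rows):
    return pd.DataFrame([
        {"trait": trait, "marker_id": f"SNP_{c}_{p}", "chrom": c, "pos": p,
         "ref": "A", "alt": "G", "method": method, "effect": eff, "se": 0.05,
         "p_value": 1e-6, "lod": 5.0, "pve": 0.05, "significant": True}
        for c, p, eff in rows
    ], columns=RESULT_COLUMNS)


res_farm = result("PT", "farmcpu", [(2, 9_506_602, -0.177)])
res_lasso = result("PT", "lasso", [(2, 9_506_602, -0.057), (5, 1_200_000, 0.07)])
res_mlm = result("PT", "single_mlm", [(2, 9_506_602, -0.244)])

calls = sg.call_qtns([res_farm, res_lasso, res_mlm])
print("QTN calls:")
print(calls[["trait", "marker_id", "methods_detected", "pleiotropic"]].to_string(index=False))

overlap = sg.cross_method_overlap(calls)
print(f"\nco-detected by >=2 methods: {overlap.n_co_detected}")
print("effect signs consistent across methods:", bool(overlap.sign_consistent.all()))

gff = """##gff-version 3
chr2\tdemo\tgene\t9300000\t9320000\t.\t+\t.\tID=geneNear
chr2\tdemo\tgene\t9900000\t9950000\t.\t-\t.\tID=geneFar
chr5\tdemo\tgene\t1100000\t1150000\t.\t+\t.\tID=geneOther
"""
with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
    fh.write(gff)
    path = fh.name

genes = sg.candidate_genes(calls, path, window=250_000)
print("\ncandidate genes within 250 kb of each QTN:")
print(genes.to_string(index=False))
print("\n(geneFar sits ~393 kb away and is correctly excluded.)")
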