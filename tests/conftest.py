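import numpy as np
import pytest

import starchgwas as sg


@pytest.fixture(scope="session")
def small_panel():
    """60 lines x 400 markers, two subpopulations, moderate LD."""
    return sg.simulate_genotype_panel(
        n=60, m=400, n_subpops=2, seed=11,
        chrom_lengths={c: 50_000_000 for c in range(1, 6)},
    )


@pytest.fixture(scope="session")
def small_kinship(small_panel):
    return sg.compute_kinship(small_panel)


@pytest.fixture(scope="session")
def small_pcs(small_panel):
    return sg.compute_pca(small_panel, k=5)


@pytest.fixture(scope="session")
def panel230():
    """230-line panel carrying markers at the eight benchmark QTL positions."""
    return sg.simulate_genotype_panel(
        n=230, m=1000, seed=7,
        required_positions=[(q.chrom, q.pos) for q in sg.BENCHMARK_QTLS],
        required_mafs=[q.maf for q in sg.BENCHMARK_QTLS],
    )


def toy_panel(dosage, chrom=None, pos=None):
    """Hand-built panel from a dosage matrix (markers get A/C alleles)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    chrom = np.asarray(chrom) if chrom is not None else np.ones(m, dtype=int)
    pos = np.asarray(pos) if pos is not None else np.arange(1, m + 1) * 1000
    return sg.GenotypePanel(
        line_ids=[f"L{i}" for i in range(n)],
        chrom=chrom,
        pos=pos,
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["C"] * m, dtype=object),
        dosage=dosage,
    )
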