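"""Genotype/phenotype file I/O and marker quality-control filters.

Two interchange formats are supported for genotypes:

* VCF 4.2 with diploid homozygous calls (``0/0``, ``1/1``; missing ``./.``),
  read through cyvcf2;
* a plain marker-matrix TSV: one row per marker with columns
  ``chrom  pos  ref  alt  <line_id_1> ... <line_id_n>`` holding dosages
  0 / 2 / NA.

The QC filter retains markers with MAF strictly above ``maf_min`` (computed
on non-missing calls) and missing fraction strictly below ``missing_max`` —
the standard "MAF above 2%, missing rate below 20%" panel rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel

log = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "read_genotypes",
    "write_genotypes",
    "filter_markers",
    "impute_missing",
    "read_phenotypes",
    "write_phenotypes",
]


@dataclass
class FilterReport:
    n_input_markers: int
    n_failed_maf: int
    n_failed_missing: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


# ----------------------------------------------------------------------
# Readers / writers
# ----------------------------------------------------------------------

def _infer_format(path: str) -> str:
    s = str(path)
    if s.endswith((".vcf", ".vcf.gz")):
        return "vcf"
    if s.endswith((".tsv", ".txt")):
        return "tsv"
    raise ValueError(f"cannot infer genotype format from {path!r}")


def read_genotypes(path, format: str | None = None, *, het_policy: str = "missing",
                   on_multiallelic: str = "error") -> GenotypePanel:
    """Read a genotype panel from VCF or marker-matrix TSV.

    ``het_policy`` controls heterozygous calls (impossible on true inbreds
    but present in real GBS data): ``"missing"`` sets them missing,
    ``"error"`` raises.  ``on_multiallelic`` is ``"error"`` or ``"skip"``.
    """
    fmt = format or _infer_format(path)
    if fmt == "vcf":
        return _read_vcf(path, het_policy, on_multiallelic)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path, het_policy: str, on_multiallelic: str) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            if on_multiallelic == "skip":
                log.warning("skipping non-biallelic-SNP record at %s:%s", v.CHROM, v.POS)
                continue
            raise ValueError(f"non-biallelic-SNP record at {v.CHROM}:{v.POS}")
        gt = np.asarray(v.gt_types)  # cyvcf2: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.full(gt.shape, np.nan)
        dos[gt == 0] = 0.0
        dos[gt == 3] = 2.0
        if (gt == 1).any():
            if het_policy == "error":
                raise ValueError(f"heterozygous call at {v.CHROM}:{v.POS}")
            # het_policy == "missing": leave as nan
        c = v.CHROM[3:] if str(v.CHROM).lower().startswith("chr") else v.CHROM
        chrom.append(int(c))
        pos.append(int(v.POS))
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(dos)
    dosage = np.vstack(rows).T if rows else np.empty((len(line_ids), 0))
    return GenotypePanel(line_ids, np.array(chrom), np.array(pos),
                         np.array(ref, dtype=object), np.array(alt, dtype=object), dosage)


def _read_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": np.int64, "pos": np.int64})
    fixed = ["chrom", "pos", "ref", "alt"]
    if df.columns[:4].tolist() != fixed:
        raise ValueError(f"genotype TSV must start with columns {fixed}")
    line_ids = df.columns[4:].tolist()
    dosage = df[line_ids].to_numpy(dtype=np.float64).T
    return GenotypePanel(
        line_ids,
        df["chrom"].to_numpy(),
        df["pos"].to_numpy(),
        df["ref"].to_numpy(dtype=object),
        df["alt"].to_numpy(dtype=object),
        dosage,
    )


def write_genotypes(panel: GenotypePanel, path, format: str | None = None) -> None:
    """Write a raw panel (dosages 0/2/missing) to VCF or TSV."""
    fmt = format or _infer_format(path)
    if fmt == "vcf":
        _write_vcf(panel, path)
    elif fmt == "tsv":
        _write_tsv(panel, path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def _write_vcf(panel: GenotypePanel, path) -> None:
    d = panel.dosage
    if not (np.isnan(d) | (d == 0) | (d == 2)).all():
        raise ValueError("VCF output requires raw dosages 0/2/missing")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=starchgwas\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(panel.chrom.tolist())):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.line_ids) + "\n")
        ids = panel.marker_ids
        for j in range(panel.n_markers):
            col = d[:, j]
            calls = np.where(np.isnan(col), "./.", np.where(col == 2.0, "1/1", "0/0"))
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{ids[j]}\t{panel.ref[j]}\t"
                f"{panel.alt[j]}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def _write_tsv(panel: GenotypePanel, path) -> None:
    df = pd.DataFrame({
        "chrom": panel.chrom, "pos": panel.pos,
        "ref": panel.ref, "alt": panel.alt,
    })
    mat = pd.DataFrame(panel.dosage.T, columns=panel.line_ids)
    pd.concat([df, mat], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV: columns line_id, optional rep_id, then trait columns."""
    df = pd.read_csv(path, sep="\t")
    if "line_id" not in df.columns:
        raise ValueError("phenotype TSV must have a line_id column")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# QC filters and imputation
# ----------------------------------------------------------------------

def filter_markers(panel: GenotypePanel, maf_min: float = 0.02,
                   missing_max: float = 0.20) -> tuple[GenotypePanel, FilterReport]:
    """Retain markers with MAF > ``maf_min`` and missing rate < ``missing_max``.

    Both bounds are strict ("above" / "below").  A marker may fail both
    filters; it is counted in each failure tally but removed once.
    """
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= missing_max <= 1.0):
        raise ValueError("thresholds must be in [0, 1]")
    maf = panel.maf
    miss = panel.missing_rate
    fail_maf = ~(maf > maf_min)  # catches nan (all-missing) as failure
    fail_miss = miss >= missing_max
    keep = ~(fail_maf | fail_miss)
    report = FilterReport(
        n_input_markers=panel.n_markers,
        n_failed_maf=int(fail_maf.sum()),
        n_failed_missing=int(fail_miss.sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        log.warning("all %d markers removed by QC filters", panel.n_markers)
    return panel.subset_markers(keep), report


def impute_missing(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing dosages by the per-marker mean of observed calls."""
    d = panel.dosage.copy()
    n_obs = (~np.isnan(d)).sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(f"marker {panel.marker_ids[j]} has no observed calls")
    if np.isnan(d).any():
        mu = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d[idx] = mu[idx[1]]
    out = panel.copy()
    out.dosage = d
    return out
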