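"""Core genotype container for inbred association panels.

Genotypes are coded as allele dosages in {0, 2} (fully homozygous inbred
lines; heterozygotes do not occur), with ``numpy.nan`` marking missing
calls.  Per-marker variance under this coding is ``4 p (1 - p)`` where
``p`` is the coded-allele frequency, which is the convention all effect
sizes in this package use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class GenotypePanel:
    """n lines x m biallelic markers with a chromosome/position map.

    Attributes
    ----------
    line_ids : list of str
        Identifiers of the inbred lines (rows of ``dosage``).
    chrom, pos : int arrays of shape (m,)
        Chromosome number (1-based) and 1-based bp position per marker.
        Positions are strictly increasing within each chromosome.
    ref, alt : str arrays of shape (m,)
        The two allele symbols per marker; dosage counts copies of ``alt``.
    dosage : float array of shape (n, m)
        Entries in {0.0, 2.0, nan} for raw panels; mean-imputed panels may
        carry fractional dosages.
    """

    line_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        if self.dosage.shape != (len(self.line_ids), self.chrom.size):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.line_ids)} lines x {self.chrom.size} markers"
            )

    # ------------------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return int(self.chrom.size)

    @property
    def marker_ids(self) -> np.ndarray:
        """Marker names in the SNP_<chrom>_<pos> convention."""
        return np.array(
            [f"SNP_{c}_{p}" for c, p in zip(self.chrom, self.pos)], dtype=object
        )

    @property
    def alt_freq(self) -> np.ndarray:
        """Coded (alt) allele frequency per marker, from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker in [0, 0.5]."""
        p = self.alt_freq
        return np.minimum(p, 1.0 - p)

    @property
    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.dosage).any()

    # ------------------------------------------------------------------
    def validate(self, raw: bool = True) -> None:
        """Check structural invariants; raise ``ValueError`` on violation.

        With ``raw=True``, dosages must be exactly {0, 2, nan}; imputed
        panels (fractional dosages in [0, 2]) pass with ``raw=False``.
        """
        d = self.dosage
        if raw:
            ok = np.isnan(d) | (d == 0.0) | (d == 2.0)
            if not ok.all():
                raise ValueError("raw dosages must be 0, 2 or missing")
        else:
            ok = np.isnan(d) | ((d >= 0.0) & (d <= 2.0))
            if not ok.all():
                raise ValueError("dosages must lie in [0, 2] or be missing")
        for a in (self.ref, self.alt):
            if any(len(str(x)) != 1 for x in a):
                raise ValueError("allele symbols must be single characters")
        if any(r == a for r, a in zip(self.ref, self.alt)):
            raise ValueError("ref and alt alleles must differ")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on chrom {c}")

    # ------------------------------------------------------------------
    def marker_index(self, chrom: int, pos: int) -> int:
        """Index of the marker at (chrom, pos); ``LookupError`` if absent."""
        hits = np.flatnonzero((self.chrom == chrom) & (self.pos == pos))
        if hits.size == 0:
            raise LookupError(f"no marker at chrom {chrom} pos {pos}")
        return int(hits[0])

    def subset_markers(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(
            line_ids=list(self.line_ids),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[:, idx],
        )

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            line_ids=list(self.line_ids),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            dosage=self.dosage.copy(),
        )


def standardized_dosage(panel: GenotypePanel, drop_invariant: bool = True):
    """Column-standardized dosage matrix W (mean 0, variance 1 per marker).

    Returns ``(W, kept)`` where ``kept`` indexes the markers retained
    (zero-variance markers are excluded when ``drop_invariant``).  The panel
    must be complete (impute first).
    """
    if not panel.is_complete:
        raise ValueError("panel has missing calls; impute before standardizing")
    d = panel.dosage
    mu = d.mean(axis=0)
    sd = d.std(axis=0)
    if drop_invariant:
        kept = np.flatnonzero(sd > 0)
    else:
        kept = np.arange(d.shape[1])
        if (sd == 0).any():
            raise ValueError("zero-variance marker in standardization")
    W = (d[:, kept] - mu[kept]) / sd[kept]
    return W, kept
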