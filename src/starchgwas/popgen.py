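"""Kinship, PCA structure control and LD decay for complete panels.

Kinship is the VanRaden-type standardized genomic relationship
K = W W' / m with W the column-standardized dosage matrix; the PC scores
are computed from the same W so they reproduce K's top eigenvectors.
LD is the composite r^2 between dosage vectors (appropriate for unphased
inbred panels), binned by physical distance within chromosomes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel, standardized_dosage

log = logging.getLogger(__name__)

__all__ = [
    "KinshipMatrix",
    "PCResult",
    "compute_kinship",
    "compute_pca",
    "ld_decay",
    "decay_distance",
]


@dataclass
class KinshipMatrix:
    values: np.ndarray
    line_ids: list[str]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.line_ids,
                     columns=self.line_ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), df.index.tolist())


@dataclass
class PCResult:
    scores: np.ndarray         # (n, k) PC scores, centered
    explained_var: np.ndarray  # (k,) variance of each score column, non-increasing
    line_ids: list[str]

    def to_tsv(self, path) -> None:
        k = self.scores.shape[1]
        df = pd.DataFrame(self.scores, columns=[f"PC{i+1}" for i in range(k)])
        df.insert(0, "line_id", self.line_ids)
        with open(path, "w") as fh:
            df.to_csv(fh, sep="\t", index=False)
            fh.write("#explained_var\t" + "\t".join(f"{v:.10g}" for v in self.explained_var) + "\n")


def compute_kinship(panel: GenotypePanel) -> KinshipMatrix:
    """Standardized (VanRaden-type) kinship K = W W' / m.

    Zero-variance markers are excluded from W with a log warning; the trace
    of K is exactly n when no markers are excluded.
    """
    W, kept = standardized_dosage(panel)
    n_dropped = panel.n_markers - kept.size
    if n_dropped:
        log.warning("excluded %d zero-variance markers from kinship", n_dropped)
    if kept.size == 0:
        raise ValueError("no polymorphic markers for kinship")
    K = W @ W.T / kept.size
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, list(panel.line_ids))


def compute_pca(panel: GenotypePanel, k: int = 5) -> PCResult:
    """Top-k principal components of the standardized dosage matrix.

    Scores are U sqrt(lambda) with lambda the eigenvalues of the kinship
    matrix K = W W'/m, i.e. the left singular vectors of W scaled by
    S/sqrt(m).  This normalization reproduces K's eigenvectors exactly and
    is invariant to duplicating markers; ``explained_var`` holds the
    eigenvalues (score-column variances scale with them and sum to at most
    trace(K) ~= n).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    W, kept = standardized_dosage(panel)
    if k > min(W.shape):
        raise ValueError(f"k={k} exceeds min(n, m) = {min(W.shape)}")
    U, S, _ = np.linalg.svd(W, full_matrices=False)
    lam = (S[:k] ** 2) / kept.size
    scores = U[:, :k] * np.sqrt(lam)
    return PCResult(scores, lam, list(panel.line_ids))


def ld_decay(panel: GenotypePanel, max_dist: int = 1_000_000,
             bin_width: int = 5_000) -> pd.DataFrame:
    """Mean pairwise r^2 binned by physical distance (same-chromosome pairs).

    Returns a frame with columns ``bin_lo``, ``bin_hi``, ``mid``,
    ``mean_r2``, ``n_pairs``; bin k covers distances in (k*w, (k+1)*w].
    """
    if not panel.is_complete:
        raise ValueError("panel has missing calls; impute before LD computation")
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for c in np.unique(panel.chrom):
        idx = np.flatnonzero(panel.chrom == c)
        if idx.size < 2:
            continue
        d = panel.dosage[:, idx]
        sd = d.std(axis=0)
        ok = sd > 0
        d, posc = d[:, ok], panel.pos[idx][ok]
        if posc.size < 2:
            continue
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(d.T)
        iu, ju = np.triu_indices(posc.size, k=1)
        dist = posc[ju] - posc[iu]
        inside = (dist > 0) & (dist <= max_dist)
        r2 = r[iu[inside], ju[inside]] ** 2
        b = ((dist[inside] - 1) // bin_width).astype(int)
        np.add.at(sums, b, r2)
        np.add.at(counts, b, 1)
    if counts.sum() == 0:
        raise ValueError("no marker pairs within max_dist on any chromosome")
    lo = np.arange(n_bins) * bin_width
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "bin_lo": lo + 1,
        "bin_hi": lo + bin_width,
        "mid": lo + bin_width / 2.0,
        "mean_r2": mean_r2,
        "n_pairs": counts,
    })


def decay_distance(table: pd.DataFrame, cutoff: float = 0.1) -> float:
    """Smallest bin midpoint where the smoothed mean r^2 falls below cutoff.

    Smoothing is a centered rolling median over 3 bins (empty bins are
    interpolated first).  If the smoothed curve never crosses the cutoff the
    largest bin edge is returned and a warning is issued.
    """
    t = table.sort_values("mid").reset_index(drop=True)
    r2 = t["mean_r2"].interpolate(limit_direction="both")
    smooth = r2.rolling(3, center=True, min_periods=1).median()
    below = np.flatnonzero(smooth.to_numpy() < cutoff)
    if below.size == 0:
        warnings.warn(f"mean r^2 never falls below {cutoff}; returning max distance")
        return float(t["bin_hi"].iloc[-1])
    return float(t["mid"].iloc[below[0]])
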