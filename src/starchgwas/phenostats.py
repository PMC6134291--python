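"""Descriptive trait statistics, correlations, and REML heritability.

Trait tables are long-format DataFrames with a ``line_id`` column, an
optional ``rep_id`` column for replicate-level records, and one column per
trait.  Heritability follows the variance-component convention

    h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)

from the one-way random-effects model y_ij = mu + g_i + e_ij fitted by
REML, with an optional fixed replicate (block) effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import fit_reml

log = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "CorrelationResult",
    "trait_columns",
    "descriptive_stats",
    "trait_correlations",
    "reml_variance_components",
    "heritability",
]

_META_COLS = ("line_id", "rep_id")


def trait_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLS]


def _line_means(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate-level records to per-line trait means."""
    traits = trait_columns(table)
    for t in traits:
        if not pd.api.types.is_numeric_dtype(table[t]):
            bad = table[t][pd.to_numeric(table[t], errors="coerce").isna()].index[0]
            raise ValueError(f"non-numeric entry in trait {t!r} at row {bad}")
    return table.groupby("line_id", sort=True)[traits].mean()


@dataclass
class VarianceComponents:
    genetic_var: float
    residual_var: float
    h2: float
    f_value: float


def heritability(sigma_g2: float, sigma_e2: float) -> float:
    """h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
    tot = sigma_g2 + sigma_e2
    if tot <= 0:
        raise ValueError("total variance must be positive")
    return sigma_g2 / tot


def descriptive_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trait mean, SD, min and max over line-level values.

    Replicate-level tables are first averaged within line, matching the
    convention of reporting each line by the mean of its biological
    replicates.
    """
    means = _line_means(table)
    return pd.DataFrame({
        "mean": means.mean(),
        "sd": means.std(ddof=1),
        "min": means.min(),
        "max": means.max(),
    })


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    sig05: pd.DataFrame
    sig01: pd.DataFrame


def trait_correlations(table: pd.DataFrame) -> CorrelationResult:
    """Pairwise Pearson correlations with two-sided t-test significance flags.

    Zero-variance traits yield NaN correlations (flagged False), not errors.
    """
    means = _line_means(table)
    if means.shape[0] < 3:
        raise ValueError("need at least 3 lines for correlation tests")
    traits = means.columns.tolist()
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x, y = means.iloc[:, i], means.iloc[:, j]
            if x.std() == 0 or y.std() == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                log.warning("zero-variance trait in pair (%s, %s)", traits[i], traits[j])
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rd = pd.DataFrame(r, index=traits, columns=traits)
    pdng = pd.DataFrame(p, index=traits, columns=traits)
    off = ~np.eye(k, dtype=bool)
    return CorrelationResult(
        r=rd,
        p=pdng,
        sig05=pd.DataFrame((p < 0.05) & off, index=traits, columns=traits),
        sig01=pd.DataFrame((p < 0.01) & off, index=traits, columns=traits),
    )


def reml_variance_components(table: pd.DataFrame, trait: str,
                             include_block: bool = False) -> VarianceComponents:
    """REML genetic/residual variances and heritability for one trait.

    Fits y_ij = mu (+ block_j) + g_i + e_ij with g_i random via the shared
    one-random-effect REML core (K = Z Z' for the line-incidence matrix Z).
    ``f_value`` is the one-way ANOVA variance ratio MS_line / MS_error.
    Negative variance components cannot occur (REML is optimized over
    non-negative ratios); a boundary solution is logged.
    """
    if "rep_id" not in table.columns:
        raise ValueError("replicate-level table with a rep_id column required")
    sub = table[["line_id", "rep_id", trait]].dropna()
    y = sub[trait].to_numpy(dtype=float)
    lines, line_idx = np.unique(sub["line_id"], return_inverse=True)
    reps, rep_idx = np.unique(sub["rep_id"], return_inverse=True)
    counts = np.bincount(line_idx)
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 replicates for >= 2 lines to separate variances")
    N, n = y.size, lines.size
    Z = np.zeros((N, n))
    Z[np.arange(N), line_idx] = 1.0
    X = np.ones((N, 1))
    if include_block and reps.size > 1:
        B = np.zeros((N, reps.size - 1))
        for r in range(1, reps.size):
            B[rep_idx == r, r - 1] = 1.0
        X = np.hstack([X, B])
    fit = fit_reml(y, X, K=Z @ Z.T)
    sg2, se2 = fit.sigma_g2, fit.sigma_e2
    if fit.delta >= 1e5 * 0.999:
        log.info("genetic variance at boundary (~0) for trait %s", trait)
        sg2 = 0.0

    # one-way ANOVA variance ratio
    grand = y.mean()
    line_means = np.array([y[line_idx == i].mean() for i in range(n)])
    ssb = float(np.sum(counts * (line_means - grand) ** 2))
    sse = float(np.sum((y - line_means[line_idx]) ** 2))
    ms_line = ssb / (n - 1)
    ms_err = sse / (N - n)
    return VarianceComponents(
        genetic_var=sg2,
        residual_var=se2,
        h2=heritability(sg2, se2) if (sg2 + se2) > 0 else np.nan,
        f_value=ms_line / ms_err,
    )


def variance_component_table(table: pd.DataFrame, include_block: bool = False) -> pd.DataFrame:
    """Descriptive stats plus variance components for every trait column."""
    desc = descriptive_stats(table)
    rows = {}
    for t in trait_columns(table):
        vc = reml_variance_components(table, t, include_block=include_block)
        rows[t] = {"genetic_var": vc.genetic_var, "residual_var": vc.residual_var,
                   "h2": vc.h2, "f_value": vc.f_value}
    return desc.join(pd.DataFrame(rows).T)
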