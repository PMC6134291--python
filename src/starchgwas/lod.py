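"""The global LOD <-> p-value bridge (1-df chi-square convention).

Declared once so the LOD > 3 rule of the multi-locus engines and the
p < 1/m rule of the single-locus scans are commensurable:

    lod = qchisq(1 - p, 1) / (2 ln 10),      p = P(chi^2_1 > 2 ln 10 * lod)

LOD 3 corresponds to a likelihood ratio of 2 ln(10^3) ~= 13.82, i.e. a
two-sided p of about 2.0e-4.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

__all__ = ["pval_to_lod", "lod_to_pval"]

_2LN10 = 2.0 * math.log(10.0)


def pval_to_lod(p):
    """Map p in (0, 1] to a LOD score; p = 0 maps to +inf."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        lod = stats.chi2.isf(p, df=1) / _2LN10
    out = np.where(p == 0.0, np.inf, lod)
    return float(out) if out.ndim == 0 else out


def lod_to_pval(lod):
    """Inverse of :func:`pval_to_lod`."""
    lod = np.asarray(lod, dtype=float)
    if (lod < 0).any():
        raise ValueError("LOD scores must be non-negative")
    p = stats.chi2.sf(lod * _2LN10, df=1)
    return float(p) if p.ndim == 0 else p
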