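"""QTN calling, cross-method overlap and candidate-gene windows.

A QTN call is one (trait, marker) pair passed by at least one engine's
native significance rule; a call is pleiotropic when the same marker is
called for two or more traits.  Candidate genes are the gene models whose
span intersects a +/- window (default 250 kb) around the QTN position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["call_qtns", "cross_method_overlap", "candidate_genes", "OverlapSummary"]


def call_qtns(results) -> pd.DataFrame:
    """Collapse per-method association results into QTN calls.

    ``results`` is an iterable of association-result DataFrames (any mix of
    methods and traits; each frame carries ``method`` and ``trait``
    columns).  Returns one row per (trait, marker) with a passing method,
    with columns ``trait``, ``marker_id``, ``chrom``, ``pos``,
    ``methods_detected`` (sorted tuple), ``effects`` / ``pves`` (dicts keyed
    by method) and the ``pleiotropic`` flag.  Deterministic and invariant
    to the order of the input frames.
    """
    frames = [df for df in results if len(df)]
    if not frames:
        return pd.DataFrame(columns=[
            "trait", "marker_id", "chrom", "pos", "methods_detected",
            "effects", "pves", "pleiotropic",
        ])
    allres = pd.concat(frames, ignore_index=True)
    key_map = allres.groupby("marker_id")[["chrom", "pos"]].nunique()
    bad = key_map[(key_map > 1).any(axis=1)]
    if len(bad):
        raise ValueError(
            f"inconsistent marker maps across methods for {bad.index.tolist()[:5]}"
        )
    sig = allres[allres["significant"]]
    rows = []
    for (trait, marker), grp in sig.groupby(["trait", "marker_id"], sort=True):
        grp = grp.sort_values("method")
        rows.append({
            "trait": trait,
            "marker_id": marker,
            "chrom": int(grp["chrom"].iloc[0]),
            "pos": int(grp["pos"].iloc[0]),
            "methods_detected": tuple(grp["method"]),
            "effects": dict(zip(grp["method"], grp["effect"])),
            "pves": dict(zip(grp["method"], grp["pve"])),
        })
    calls = pd.DataFrame(rows)
    if len(calls):
        counts = calls.groupby("marker_id")["trait"].nunique()
        calls["pleiotropic"] = calls["marker_id"].map(counts) >= 2
        calls = calls.sort_values(["trait", "chrom", "pos"]).reset_index(drop=True)
    else:
        calls["pleiotropic"] = pd.Series(dtype=bool)
    return calls


@dataclass
class OverlapSummary:
    per_method_counts: pd.Series
    co_detected: pd.DataFrame      # calls detected by >= 2 methods
    n_co_detected: int
    sign_consistent: pd.Series     # per co-detected call: effects share sign


def cross_method_overlap(calls: pd.DataFrame) -> OverlapSummary:
    """Per-method call counts, co-detection set and sign-consistency check.

    For each (trait, marker) call detected by two or more methods, the
    sign-consistency flag is True when all reported effects share a sign —
    the behavior expected of a real association, whatever the effect
    magnitudes each engine assigns.
    """
    if len(calls) == 0:
        return OverlapSummary(pd.Series(dtype=int), calls.copy(), 0, pd.Series(dtype=bool))
    counts: dict[str, int] = {}
    for methods in calls["methods_detected"]:
        for mth in methods:
            counts[mth] = counts.get(mth, 0) + 1
    co = calls[calls["methods_detected"].apply(len) >= 2].copy()
    sign_ok = co.apply(
        lambda row: len({np.sign(v) for v in row["effects"].values() if v != 0}) <= 1,
        axis=1,
    ) if len(co) else pd.Series(dtype=bool)
    return OverlapSummary(
        per_method_counts=pd.Series(counts).sort_index(),
        co_detected=co.reset_index(drop=True),
        n_co_detected=len(co),
        sign_consistent=sign_ok.reset_index(drop=True) if len(co) else sign_ok,
    )


def _load_genes(gff3_path) -> pd.DataFrame:
    """Gene features (id, chrom, start, end) from a GFF3 file."""
    import gffutils

    # quick structural validation so malformed lines are reported with numbers
    with open(gff3_path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(f"malformed GFF3 record at line {i}: expected 9 columns")
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        c = feat.seqid[3:] if feat.seqid.lower().startswith("chr") else feat.seqid
        rows.append({"gene_id": gid, "chrom": int(c), "start": feat.start, "end": feat.end})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def candidate_genes(calls: pd.DataFrame, gff3_path, window: int = 250_000) -> pd.DataFrame:
    """Genes whose span intersects +/- ``window`` bp of each QTN (inclusive).

    Output has one row per (QTN, gene) sorted by distance from the QTN
    (0 for genes overlapping the QTN position), independent of GFF3 record
    order.
    """
    genes = _load_genes(gff3_path)
    rows = []
    markers = calls[["marker_id", "chrom", "pos"]].drop_duplicates()
    for _, q in markers.iterrows():
        lo, hi = q["pos"] - window, q["pos"] + window
        near = genes[(genes["chrom"] == q["chrom"])
                     & (genes["end"] >= lo) & (genes["start"] <= hi)]
        for _, g in near.iterrows():
            dist = max(0, g["start"] - q["pos"], q["pos"] - g["end"])
            rows.append({
                "marker_id": q["marker_id"], "chrom": q["chrom"], "pos": q["pos"],
                "gene_id": g["gene_id"], "gene_start": g["start"],
                "gene_end": g["end"], "distance": int(dist),
            })
    out = pd.DataFrame(rows, columns=[
        "marker_id", "chrom", "pos", "gene_id", "gene_start", "gene_end", "distance",
    ])
    return out.sort_values(["marker_id", "distance", "gene_id"]).reset_index(drop=True)


def calls_to_tsv(calls: pd.DataFrame, path) -> None:
    """Write QTN calls with methods flattened to a readable TSV."""
    flat = calls.copy()
    if len(flat):
        flat["methods_detected"] = flat["methods_detected"].apply(",".join)
        flat["effects"] = flat["effects"].apply(
            lambda d: ";".join(f"{k}={v:.6g}" for k, v in d.items()))
        flat["pves"] = flat["pves"].apply(
            lambda d: ";".join(f"{k}={v:.6g}" for k, v in d.items()))
    flat.to_csv(path, sep="\t", index=False)
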