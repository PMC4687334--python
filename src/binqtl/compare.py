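"""Cross-population QTL comparison and gene colocalization.

Legacy marker maps often carry physical coordinates for only a subset of
markers ("informative" anchors).  Physical positions of the remaining
markers are imputed from the regional Mb/cM rate between flanking anchors;
QTL support intervals are then compared as physical spans, and cloned genes
are located inside support intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["impute_physical", "overlap_qtls", "colocalize_genes"]


def impute_physical(markers: pd.DataFrame, chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Assign physical positions to markers lacking them.

    ``markers`` columns: marker_id, chrom, cm, pos (pos NaN for
    non-informative markers).  Within each region between consecutive
    anchors, bp(m) = bp(left) + (cm(m) - cm(left)) * regional Mb-per-cM
    rate; markers outside the outermost anchors extrapolate with the
    nearest region's rate, clipped to [1, chromosome length] when lengths
    are given.  Requires >= 2 anchors per chromosome.
    """
    out = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        sub = sub.sort_values("cm", kind="mergesort").reset_index(drop=True)
        anchors = sub.dropna(subset=["pos"])
        if len(anchors) < 2:
            raise ValueError(f"chromosome {chrom}: need >= 2 informative markers")
        acm = anchors["cm"].to_numpy(dtype=float)
        abp = anchors["pos"].to_numpy(dtype=float)
        if np.any(np.diff(acm) <= 0):
            dup = acm[np.flatnonzero(np.diff(acm) <= 0)]
            raise ValueError(f"chromosome {chrom}: anchors at identical cM ({dup[:3]}...)")
        if np.any(np.diff(abp) <= 0):
            raise ValueError(f"chromosome {chrom}: anchor bp not increasing with cM")
        cm = sub["cm"].to_numpy(dtype=float)
        bp = np.interp(cm, acm, abp)
        # extrapolate with nearest region's rate beyond the outer anchors
        rate_first = (abp[1] - abp[0]) / (acm[1] - acm[0])
        rate_last = (abp[-1] - abp[-2]) / (acm[-1] - acm[-2])
        below = cm < acm[0]
        above = cm > acm[-1]
        bp[below] = abp[0] + (cm[below] - acm[0]) * rate_first
        bp[above] = abp[-1] + (cm[above] - acm[-1]) * rate_last
        if chrom_lengths and chrom in chrom_lengths:
            bp = np.clip(bp, 1, chrom_lengths[chrom])
        else:
            bp = np.maximum(bp, 1)
        filled = sub.copy()
        filled["pos"] = np.where(sub["pos"].notna(), sub["pos"], np.round(bp))
        filled["imputed"] = sub["pos"].isna()
        out.append(filled)
    return pd.concat(out, ignore_index=True)


def overlap_qtls(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    require_same_trait: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Physical-interval overlaps between two QTL record sets.

    Records need columns trait, chrom, bp_lo, bp_hi.  Two intervals overlap
    iff their spans intersect on the same chromosome (and the same trait
    unless ``require_same_trait`` is False).  Returns (pairs with Jaccard of
    the spans, A-specific records, B-specific records).
    """
    pairs = []
    hit_a: set[int] = set()
    hit_b: set[int] = set()
    for ia, qa in records_a.reset_index(drop=True).iterrows():
        for ib, qb in records_b.reset_index(drop=True).iterrows():
            if qa["chrom"] != qb["chrom"]:
                continue
            if require_same_trait and qa["trait"] != qb["trait"]:
                continue
            lo = max(qa["bp_lo"], qb["bp_lo"])
            hi = min(qa["bp_hi"], qb["bp_hi"])
            if hi < lo:
                continue
            union = max(qa["bp_hi"], qb["bp_hi"]) - min(qa["bp_lo"], qb["bp_lo"])
            jac = (hi - lo) / union if union > 0 else 1.0
            pairs.append(
                (qa["trait"], qa["chrom"], ia, ib, qa["bp_lo"], qa["bp_hi"],
                 qb["bp_lo"], qb["bp_hi"], lo, hi, jac)
            )
            hit_a.add(ia)
            hit_b.add(ib)
    pair_frame = pd.DataFrame(
        pairs,
        columns=["trait", "chrom", "index_a", "index_b", "a_lo", "a_hi",
                 "b_lo", "b_hi", "ov_lo", "ov_hi", "jaccard"],
    )
    only_a = records_a.reset_index(drop=True).drop(index=sorted(hit_a))
    only_b = records_b.reset_index(drop=True).drop(index=sorted(hit_b))
    return pair_frame, only_a, only_b


def colocalize_genes(records: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Genes located inside QTL support intervals.

    ``genes`` columns: gene_id, chrom, start, end.  Genes fully inside
    [bp_lo, bp_hi] are reported with partial=False; boundary-straddling
    genes are reported with partial=True rather than excluded.  The
    distance from the QTL peak (bp, 0 when the peak lies inside the gene)
    uses the record's ``peak_bp`` when present, else the interval midpoint.
    """
    rows = []
    for ir, q in records.reset_index(drop=True).iterrows():
        peak = q["peak_bp"] if "peak_bp" in q and not pd.isna(q.get("peak_bp")) else (
            (q["bp_lo"] + q["bp_hi"]) / 2.0
        )
        for _, g in genes.iterrows():
            if g["chrom"] != q["chrom"]:
                continue
            if g["end"] < q["bp_lo"] or g["start"] > q["bp_hi"]:
                continue
            partial = g["start"] < q["bp_lo"] or g["end"] > q["bp_hi"]
            dist = 0.0 if g["start"] <= peak <= g["end"] else min(
                abs(g["start"] - peak), abs(g["end"] - peak)
            )
            rows.append(
                (ir, q.get("trait"), g["gene_id"], q["chrom"], g["start"], g["end"],
                 bool(partial), float(dist))
            )
    return pd.DataFrame(
        rows,
        columns=["qtl_index", "trait", "gene_id", "chrom", "gene_start", "gene_end",
                 "partial", "distance_from_peak"],
    )
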