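"""Map quality control: misassembly detection, IBD SNP verification, and
integrated-map assembly.

A genomic segment placed on the wrong chromosome in the reference assembly
betrays itself in a bin map as an excess of apparent double crossovers:
many lines show a short run of bins whose genotype differs from both
physical flanks.  Such segments are flagged, and a better placement is
searched by two-point linkage of the segment's consensus genotype against
all other bins; a relocation is accepted only when it strictly reduces the
population double-crossover count.

IBD verification exploits the fact that every SNP inside a recombination
bin shares the bin marker's parental origin in each line: observed reads
that agree with the expected parent verify the SNP, disagreements are
contradictions, and SNPs verified at least once are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .binmap import A, B, BinMap, U
from .linkmap import rf_matrices
from .tables import ObservationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DxoProfile",
    "scan_double_crossovers",
    "relocate_segment",
    "verify_snps_ibd",
    "build_integrated_map",
    "marker_density_windows",
    "concordance_tally",
    "effective_sites",
]

DEFAULT_MAX_SPAN_BP = 2_000_000


@dataclass
class DxoProfile:
    """Per-bin double-crossover counts and flagged candidate segments."""

    counts: np.ndarray  # per bin, number of lines with a double-crossover run covering it
    threshold: float
    flagged: list[tuple[int, int]]  # [start_bin, end_bin] inclusive index ranges


def _dxo_counts(binmap: BinMap, max_span_bp: int = DEFAULT_MAX_SPAN_BP) -> np.ndarray:
    """Lines in which a bin sits inside a short run whose genotype differs
    from both physical flanks (U bins are transparent)."""
    counts = np.zeros(binmap.n_bins, dtype=np.int64)
    bins = binmap.bins
    for chrom, sub in bins.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        g = binmap.genotypes[:, idx]
        for li in range(g.shape[0]):
            row = g[li]
            known = np.flatnonzero(row != U)
            if known.size < 3:
                continue
            vals = row[known]
            change = np.flatnonzero(np.concatenate(([True], vals[1:] != vals[:-1])))
            run_start = known[change]
            run_end = known[np.concatenate((change[1:] - 1, [vals.size - 1]))]
            for k in range(1, len(run_start) - 1):
                if vals[change[k - 1]] != vals[change[k + 1]]:
                    continue  # flanks must agree for a double-crossover signature
                span = ends[run_end[k]] - starts[run_start[k]]
                if span <= max_span_bp:
                    counts[idx[run_start[k] : run_end[k] + 1]] += 1
    return counts


def scan_double_crossovers(
    binmap: BinMap,
    median_factor: float = 5.0,
    min_bins: int = 2,
    min_lines_frac: float = 0.10,
    max_span_bp: int = DEFAULT_MAX_SPAN_BP,
    trim_frac: float = 0.6,
) -> DxoProfile:
    """Flag contiguous bin runs with an excess of double-crossover events.

    A bin's count is the number of lines in which it lies inside a
    same-genotype run (physical span <= ``max_span_bp``) flanked on both
    sides by a different genotype.  Bins whose count exceeds
    max(``median_factor`` x genome-wide median, ``min_lines_frac`` x lines)
    are candidates; contiguous candidate runs of >= ``min_bins`` bins are
    flagged.  Run edges with counts below ``trim_frac`` x the run maximum
    are trimmed off: bins adjacent to a misplaced block inherit elevated
    counts (ordinary segments ending at the block count as double
    crossovers) but stay well below the block's own signature.
    """
    counts = _dxo_counts(binmap, max_span_bp)
    threshold = max(median_factor * float(np.median(counts)),
                    min_lines_frac * len(binmap.line_ids))
    hot = counts > threshold
    flagged: list[tuple[int, int]] = []
    for chrom, sub in binmap.bins.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        h = hot[idx]
        k = 0
        while k < len(h):
            if not h[k]:
                k += 1
                continue
            e = k
            while e + 1 < len(h) and h[e + 1]:
                e += 1
            s2, e2 = k, e
            peak = counts[idx[k : e + 1]].max()
            while s2 <= e2 and counts[idx[s2]] < trim_frac * peak:
                s2 += 1
            while e2 >= s2 and counts[idx[e2]] < trim_frac * peak:
                e2 -= 1
            if e2 - s2 + 1 >= min_bins:
                flagged.append((int(idx[s2]), int(idx[e2])))
            k = e + 1
    return DxoProfile(counts=counts, threshold=threshold, flagged=flagged)


def _segment_consensus(binmap: BinMap, start: int, end: int) -> np.ndarray:
    """Per-line majority genotype over a bin range (A/B only; else U)."""
    block = binmap.genotypes[:, start : end + 1]
    na = (block == A).sum(axis=1)
    nb = (block == B).sum(axis=1)
    out = np.full(block.shape[0], U, dtype=np.int8)
    out[na > nb] = A
    out[nb > na] = B
    return out


def _total_dxo(binmap: BinMap) -> int:
    return int(_dxo_counts(binmap).sum())


def _moved_binmap(binmap: BinMap, start: int, end: int, dest_after: int,
                  dest_chrom: str | None = None) -> BinMap:
    """Bin map with bins [start..end] re-inserted after bin index
    ``dest_after`` (-1 inserts at the front of the whole table), re-sorted
    into the destination chromosome's coordinate frame only logically (bin
    order defines physical adjacency for double-crossover counting)."""
    n = binmap.n_bins
    seg = list(range(start, end + 1))
    rest = [k for k in range(n) if k not in seg]
    if dest_after in seg:
        raise ValueError("destination inside the segment")
    pos_in_rest = rest.index(dest_after) + 1 if dest_after >= 0 else 0
    new_order = rest[:pos_in_rest] + seg + rest[pos_in_rest:]
    bins = binmap.bins.iloc[new_order].reset_index(drop=True)
    if dest_chrom is None:
        dest_chrom = (
            binmap.bins.iloc[dest_after]["chrom"] if dest_after >= 0
            else bins.iloc[len(seg)]["chrom"]
        )
    bins.loc[pos_in_rest : pos_in_rest + len(seg) - 1, "chrom"] = dest_chrom
    return replace(binmap, bins=bins, genotypes=binmap.genotypes[:, new_order])


def relocate_segment(
    binmap: BinMap,
    segment: tuple[int, int],
    refine_bins: int = 10,
) -> dict:
    """Propose the linkage-optimal placement for a flagged bin segment.

    Evaluates the two-point LOD of the segment's consensus genotype against
    every other bin to find the best-linked region, then refines the exact
    insertion point among candidate placements within ``refine_bins`` bins
    of the best-linked bin by minimizing the total population
    double-crossover count (the same quantity that justifies the move).
    The proposal is accepted only if it strictly reduces that count.

    Returns a dict with keys proposal_after (bin index the segment is
    placed after on the destination chromosome; -1 = chromosome front),
    dest_chrom, accepted, dxo_before, dxo_after, and the relocated BinMap
    under 'binmap' (the original when rejected).
    """
    start, end = segment
    consensus = _segment_consensus(binmap, start, end)
    others = [k for k in range(binmap.n_bins) if k < start or k > end]
    g = np.column_stack([consensus, binmap.genotypes[:, others]])
    _r, lod, _n = rf_matrices(g)
    link = lod[0, 1:]
    best = others[int(np.argmax(link))]
    chrom = binmap.bins.iloc[best]["chrom"]
    same = [k for k in binmap.bins.index[binmap.bins["chrom"] == chrom] if k < start or k > end]
    bpos = same.index(best)
    lo = max(0, bpos - refine_bins)
    hi = min(len(same) - 1, bpos + refine_bins)
    candidates = []
    if lo == 0:
        prev = [k for k in others if k < same[0]]
        candidates.append(int(prev[-1]) if prev else -1)  # chromosome front
    candidates.extend(int(same[k]) for k in range(lo, hi + 1))

    before = _total_dxo(binmap)
    best_after, best_count, best_map = None, None, None
    for dest in candidates:
        moved = _moved_binmap(binmap, start, end, dest, dest_chrom=str(chrom))
        count = _total_dxo(moved)
        if best_count is None or count < best_count:
            best_after, best_count, best_map = dest, count, moved
    accepted = best_count is not None and best_count < before
    if not accepted:
        logger.warning("no placement reduces double-crossovers; segment retained")
    return {
        "segment": segment,
        "best_bin": int(best),
        "proposal_after": best_after,
        "dest_chrom": str(chrom),
        "dxo_before": before,
        "dxo_after": best_count,
        "accepted": bool(accepted),
        "binmap": best_map if accepted else binmap,
    }


def verify_snps_ibd(
    snps: pd.DataFrame,
    obs: ObservationMatrix,
    binmap: BinMap,
    exclude_contradicted: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """IBD-based verification of parental SNPs against the bin map.

    For every line x SNP with at least one read, the expected allele is the
    parent of the containing bin's genotype in that line (H/U bins
    contribute nothing); the observed call is the majority read allele
    (ties uncounted).  A SNP is retained when verified at least once; with
    ``exclude_contradicted`` any contradiction excludes it.

    Returns (tally, retained_snps); tally columns: snp_id, verified,
    contradicted, covered, status.
    """
    obs = obs.reindex_snps(snps) if list(obs.snps["snp_id"]) != list(snps["snp_id"]) else obs
    n_snps = len(snps)
    verified = np.zeros(n_snps, dtype=np.int64)
    contradicted = np.zeros(n_snps, dtype=np.int64)
    in_bin = np.zeros(n_snps, dtype=bool)
    observed_call = np.where(obs.n_p1 > obs.n_p2, A, np.where(obs.n_p2 > obs.n_p1, B, U))
    observed_call[(obs.n_p1 + obs.n_p2) == 0] = U
    for chrom, sub in snps.groupby("chrom", sort=False):
        cols = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        cbins = binmap.bins[binmap.bins["chrom"] == chrom]
        if cbins.empty:
            logger.warning("no bins on %s: %d SNPs uncounted", chrom, len(sub))
            continue
        starts = cbins["start"].to_numpy()
        ends = cbins["end"].to_numpy()
        bidx = cbins.index.to_numpy()
        k = np.searchsorted(starts, pos - 1, side="right") - 1
        ok = (k >= 0) & ((pos - 1) < ends[np.clip(k, 0, len(ends) - 1)])
        if (~ok).any():
            logger.warning("%d SNPs on %s fall outside any bin", int((~ok).sum()), chrom)
        in_bin[cols[ok]] = True
        expected = np.full((len(obs.line_ids), len(sub)), U, dtype=np.int8)
        expected[:, ok] = binmap.genotypes[:, bidx[k[ok]]]
        expected[(expected != A) & (expected != B)] = U
        oc = observed_call[:, cols]
        informative = (oc != U) & (expected != U)
        verified[cols] += (informative & (oc == expected)).sum(axis=0)
        contradicted[cols] += (informative & (oc != expected)).sum(axis=0)
    status = np.where(
        (verified >= 1) & (~(exclude_contradicted & (contradicted > 0))),
        "retained",
        "excluded",
    )
    tally = pd.DataFrame(
        {
            "snp_id": snps["snp_id"].to_numpy(),
            "verified": verified,
            "contradicted": contradicted,
            "in_bin": in_bin,
            "status": status,
        }
    )
    retained = snps[status == "retained"].reset_index(drop=True)
    return tally, retained


def build_integrated_map(marker_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge marker classes into one physically sorted table.

    ``marker_sets`` maps a class name (e.g. 'traditional', 'bin', 'snp') to
    a frame with marker_id, chrom, pos.  Coordinate collisions across
    classes are kept and flagged.
    """
    frames = []
    for cls, frame in marker_sets.items():
        sub = frame[["marker_id", "chrom", "pos"]].copy()
        sub["class"] = cls
        frames.append(sub)
    merged = pd.concat(frames, ignore_index=True)
    merged = merged.sort_values(["chrom", "pos", "class"], kind="mergesort").reset_index(drop=True)
    merged["collision"] = merged.duplicated(subset=["chrom", "pos"], keep=False)
    return merged


def marker_density_windows(integrated: pd.DataFrame, window_bp: int = 10_000_000) -> pd.DataFrame:
    """Per-class marker counts in non-overlapping half-open windows
    [k*window, (k+1)*window)."""
    tmp = integrated.copy()
    tmp["window"] = (tmp["pos"] - 1) // window_bp
    counts = tmp.groupby(["chrom", "window", "class"]).size().unstack(fill_value=0)
    counts = counts.reset_index()
    counts["start"] = counts["window"] * window_bp
    counts["end"] = counts["start"] + window_bp
    return counts


def effective_sites(total: int, missing: int, heterozygous: int) -> int:
    """Effective genotype combinations: total minus missing minus
    heterozygous (heterozygous calls are errors in a DH/inbred context)."""
    return int(total - missing - heterozygous)


def concordance_tally(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> dict:
    """Concordance between two genotype call sets over a shared
    (sample, marker) index.

    Call frames have columns sample, marker, genotype with missing encoded
    as NaN/None/'' and heterozygous as 'H'.  Returns a dict with total,
    missing, heterozygous, effective, consistent and percent (1 decimal).
    """
    a = calls_a.set_index(["sample", "marker"])["genotype"]
    b = calls_b.set_index(["sample", "marker"])["genotype"]
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError("call sets share no (sample, marker) index")
    a, b = a.loc[shared], b.loc[shared]
    missing = a.isna() | b.isna() | (a == "") | (b == "")
    het = (~missing) & ((a == "H") | (b == "H"))
    eff = ~missing & ~het
    consistent = int((a[eff] == b[eff]).sum())
    n_eff = int(eff.sum())
    return {
        "total": int(len(shared)),
        "missing": int(missing.sum()),
        "heterozygous": int(het.sum()),
        "effective": n_eff,
        "consistent": consistent,
        "percent": round(100.0 * consistent / n_eff, 1) if n_eff else float("nan"),
    }
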