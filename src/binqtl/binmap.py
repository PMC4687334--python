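"""Sliding-window genotype calling and recombination-bin construction.

Each line is genotyped along every chromosome with a window of a fixed count
of *observed* SNPs (default 15), so the physical window span adapts to the
line's read density.  Window calls come from the ratio of reads supporting
each parental allele; transitions between collapsed runs of calls yield
recombination breakpoints; 100-kb grid intervals are genotyped by the call
covering their midpoint; and population-wide bins merge adjacent intervals
that no line separates with a genotype change.

Genotype codes used throughout: 0 = A (parent 1), 1 = B (parent 2),
2 = H (heterozygous), 3 = U (unknown/missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import ObservationMatrix

logger = logging.getLogger(__name__)

A, B, H, U = 0, 1, 2, 3
GENO_LETTERS = np.array(["A", "B", "H", "U"])
DEFAULT_GRID = 100_000

__all__ = [
    "A",
    "B",
    "H",
    "U",
    "WindowCalls",
    "Breakpoint",
    "BinMap",
    "call_windows",
    "detect_breakpoints",
    "genotype_intervals",
    "build_binmap",
    "binmap_from_observations",
    "bin_length_summary",
    "mean_breakpoints_per_line",
]


@dataclass
class WindowCalls:
    """Window-level calls for one line on one chromosome.

    ``span_start``/``span_end`` are the bp of the first/last observed SNP in
    each window; ``n_p1``/``n_p2`` are summed read-allele counts.
    """

    line: str
    chrom: str
    span_start: np.ndarray
    span_end: np.ndarray
    n_p1: np.ndarray
    n_p2: np.ndarray
    call: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.call)


@dataclass(frozen=True)
class Breakpoint:
    line: str
    chrom: str
    pos: int  # midpoint of the transition gap, bp
    left: int  # genotype code of the run to the left
    right: int


def _classify(n1: np.ndarray, n2: np.ndarray, n_both: np.ndarray, window_size: int,
              h: float, het_min_frac: float) -> np.ndarray:
    """Vectorized window-call rule.

    ``n_both`` counts SNPs in the window whose own reads show *both*
    parental alleles — the only read pattern that distinguishes residual
    heterozygosity from a breakpoint-spanning mixture of pure SNPs.
    """
    total = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, n1 / np.maximum(total, 1), np.nan)
    call = np.full(n1.shape, U, dtype=np.int8)
    call[ratio >= h] = A
    call[ratio <= 1.0 - h] = B
    het = (
        (ratio > 1.0 - h)
        & (ratio < h)
        & (n_both >= het_min_frac * window_size)
    )
    call[het] = H
    return call


def call_windows(
    obs: ObservationMatrix,
    window_size: int = 15,
    h: float = 0.7,
    het_min_frac: float = 0.3,
) -> list[WindowCalls]:
    """Sliding-window calls for every line x chromosome.

    The window advances one observed SNP at a time over the SNPs with at
    least one read in the line (a fixed *observed*-SNP count, so the physical
    span is dynamic).  A window is called A when the parent-1 read fraction
    is >= ``h``, B when <= 1-h; in between it is H only when at least
    ``het_min_frac * window_size`` of its SNPs individually show both
    parental alleles (so a breakpoint-spanning mixture of pure SNPs is U,
    never H); otherwise U.
    """
    if window_size < 3:
        raise ValueError("window_size must be >= 3")
    if not 0.5 < h <= 1.0:
        raise ValueError("h must be in (0.5, 1]")
    out: list[WindowCalls] = []
    snps = obs.snps
    for chrom, sub in snps.groupby("chrom", sort=False):
        cols = sub.index.to_numpy()
        pos = sub["pos"].to_numpy(dtype=np.int64)
        c1 = obs.n_p1[:, cols]
        c2 = obs.n_p2[:, cols]
        covered = (c1 + c2) > 0
        for li, line in enumerate(obs.line_ids):
            mask = covered[li]
            k = int(mask.sum())
            if k == 0:
                logger.debug("line %s has no observations on %s", line, chrom)
                continue
            if k < window_size:
                logger.debug("line %s: %d observed SNPs < window on %s", line, k, chrom)
                continue
            p = pos[mask]
            kernel = np.ones(window_size, dtype=np.int64)
            w1 = np.convolve(c1[li, mask], kernel, "valid")
            w2 = np.convolve(c2[li, mask], kernel, "valid")
            both = ((c1[li, mask] > 0) & (c2[li, mask] > 0)).astype(np.int64)
            wb = np.convolve(both, kernel, "valid")
            call = _classify(w1, w2, wb, window_size, h, het_min_frac)
            out.append(
                WindowCalls(
                    line=line,
                    chrom=str(chrom),
                    span_start=p[: k - window_size + 1],
                    span_end=p[window_size - 1 :],
                    n_p1=w1,
                    n_p2=w2,
                    call=call,
                )
            )
    return out


def _runs(call: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse non-U windows into maximal runs of an identical call.

    Returns (values, first_window_index, last_window_index); U windows are
    skipped and never break a run.
    """
    idx = np.flatnonzero(call != U)
    if idx.size == 0:
        return np.empty(0, np.int8), np.empty(0, np.int64), np.empty(0, np.int64)
    vals = call[idx]
    new = np.flatnonzero(np.concatenate(([True], vals[1:] != vals[:-1])))
    starts = idx[new]
    ends = idx[np.concatenate((new[1:] - 1, [vals.size - 1]))]
    return vals[new], starts, ends


def _smooth_isolated(call: np.ndarray) -> np.ndarray:
    """Set single-window runs that disagree with both flanking runs to U."""
    call = call.copy()
    vals, starts, ends = _runs(call)
    for k in range(len(vals)):
        if starts[k] == ends[k] and 0 < k < len(vals) - 1:
            if vals[k - 1] != vals[k] and vals[k + 1] != vals[k]:
                call[starts[k]] = U
    return call


def detect_breakpoints(calls: WindowCalls, smooth: bool = True) -> list[Breakpoint]:
    """Breakpoints of one line on one chromosome.

    Isolated single-window outliers are smoothed away first (configurable);
    each transition between collapsed runs yields one breakpoint at the
    midpoint between the last SNP of the left run's defining window span and
    the first SNP of the right run's.
    """
    call = _smooth_isolated(calls.call) if smooth else calls.call
    vals, starts, ends = _runs(call)
    bps: list[Breakpoint] = []
    for k in range(1, len(vals)):
        left_bp = calls.span_end[ends[k - 1]]
        right_bp = calls.span_start[starts[k]]
        bps.append(
            Breakpoint(
                line=calls.line,
                chrom=calls.chrom,
                pos=int((int(left_bp) + int(right_bp)) // 2),
                left=int(vals[k - 1]),
                right=int(vals[k]),
            )
        )
    return bps


def genotype_intervals(
    calls: WindowCalls,
    breakpoints: list[Breakpoint],
    chrom_length: int,
    grid: int = DEFAULT_GRID,
    smooth: bool = True,
) -> np.ndarray:
    """Per-interval genotypes of one line on one chromosome.

    Every ``grid``-bp interval takes the call of the run covering its
    midpoint; a midpoint that coincides exactly with a breakpoint takes the
    *left* run's call; intervals whose midpoint lies outside the outermost
    informative window span are U.
    """
    n_int = int(np.ceil(chrom_length / grid))
    out = np.full(n_int, U, dtype=np.int8)
    call = _smooth_isolated(calls.call) if smooth else calls.call
    vals, starts, ends = _runs(call)
    if len(vals) == 0:
        return out
    mids = np.arange(n_int, dtype=np.int64) * grid + grid // 2
    first_bp = int(calls.span_start[starts[0]])
    last_bp = int(calls.span_end[ends[-1]])
    inside = (mids >= first_bp) & (mids <= last_bp)
    bp_pos = np.array([b.pos for b in breakpoints], dtype=np.int64)
    run_idx = np.searchsorted(bp_pos, mids, side="left")
    out[inside] = vals[run_idx[inside]]
    return out


@dataclass
class BinMap:
    """Population recombination-bin map.

    ``bins`` has columns chrom, start, end (half-open, multiples of the
    grid), marker_id and pos (floor midpoint, the virtual bin-marker
    position); ``genotypes`` is lines x bins with codes A/B/H/U.
    """

    bins: pd.DataFrame
    genotypes: np.ndarray
    line_ids: list[str]
    grid: int = DEFAULT_GRID
    breakpoints: list[Breakpoint] | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def lengths_bp(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()

    def genotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            GENO_LETTERS[self.genotypes],
            index=pd.Index(self.line_ids, name="line"),
            columns=self.bins["marker_id"],
        )

    def marker_positions(self) -> pd.DataFrame:
        return self.bins[["marker_id", "chrom", "pos"]].copy()


def _bin_boundaries(matrix: np.ndarray) -> np.ndarray:
    """Gap indices t where any line changes genotype between interval t and
    t+1 (U forward-filled first, so A U B changes at the B side)."""
    filled = matrix.copy()
    for t in range(1, filled.shape[1]):
        miss = filled[:, t] == U
        filled[miss, t] = filled[miss, t - 1]
    left, right = filled[:, :-1], filled[:, 1:]
    change = (left != right) & (left != U) & (right != U)
    return np.flatnonzero(change.any(axis=0))


def _bin_genotype(block: np.ndarray) -> np.ndarray:
    """Per-line consensus over a bin's intervals: the (majority) non-U code."""
    counts = np.stack([(block == c).sum(axis=1) for c in (A, B, H)], axis=1)
    maj = counts.argmax(axis=1).astype(np.int8)
    return np.where(counts.sum(axis=1) > 0, maj, U).astype(np.int8)


def build_binmap(
    interval_genotypes: dict[str, np.ndarray],
    line_ids: list[str],
    grid: int = DEFAULT_GRID,
    breakpoints: list[Breakpoint] | None = None,
) -> BinMap:
    """Merge adjacent grid intervals that no line separates into bins.

    ``interval_genotypes`` maps chromosome -> (n_lines, n_intervals) code
    matrix on a shared grid.  Population bin boundaries fall wherever any
    line changes genotype between adjacent intervals; each chromosome
    contributes at least one bin.
    """
    rows = []
    geno_cols = []
    for chrom, matrix in interval_genotypes.items():
        if matrix.shape[0] != len(line_ids):
            raise ValueError("inconsistent interval grids across lines")
        edges = np.concatenate(([0], _bin_boundaries(matrix) + 1, [matrix.shape[1]]))
        for s, e in zip(edges[:-1], edges[1:]):
            start, end = int(s) * grid, int(e) * grid
            mid = (start + end) // 2
            rows.append((chrom, start, end, f"{chrom}.{mid / grid:g}", mid))
            geno_cols.append(_bin_genotype(matrix[:, s:e]))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "marker_id", "pos"])
    genotypes = (
        np.stack(geno_cols, axis=1) if geno_cols else np.empty((len(line_ids), 0), np.int8)
    )
    return BinMap(bins=bins, genotypes=genotypes, line_ids=list(line_ids), grid=grid,
                  breakpoints=breakpoints)


def binmap_from_observations(
    obs: ObservationMatrix,
    chrom_lengths: dict[str, int] | None = None,
    grid: int = DEFAULT_GRID,
    window_size: int = 15,
    h: float = 0.7,
    het_min_frac: float = 0.3,
    smooth: bool = True,
) -> BinMap:
    """Full per-line pipeline: windows -> breakpoints -> intervals -> bins."""
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(np.ceil(sub["pos"].max() / grid) * grid)
            for c, sub in obs.snps.groupby("chrom", sort=False)
        }
    calls = call_windows(obs, window_size=window_size, h=h, het_min_frac=het_min_frac)
    chroms = list(dict.fromkeys(obs.snps["chrom"]))
    n_int = {c: int(np.ceil(chrom_lengths[c] / grid)) for c in chroms}
    interval_genotypes = {
        c: np.full((len(obs.line_ids), n_int[c]), U, dtype=np.int8) for c in chroms
    }
    line_index = {line: k for k, line in enumerate(obs.line_ids)}
    all_bps: list[Breakpoint] = []
    for wc in calls:
        bps = detect_breakpoints(wc, smooth=smooth)
        all_bps.extend(bps)
        interval_genotypes[wc.chrom][line_index[wc.line]] = genotype_intervals(
            wc, bps, chrom_lengths[wc.chrom], grid=grid, smooth=smooth
        )
    return build_binmap(interval_genotypes, obs.line_ids, grid=grid, breakpoints=all_bps)


_LENGTH_CLASSES = [
    ("<1Mb", 0, 1_000_000),
    ("1-10Mb", 1_000_000, 10_000_000),
    ("10-20Mb", 10_000_000, 20_000_000),
    (">=20Mb", 20_000_000, np.inf),
]


def bin_length_summary(lengths_bp: np.ndarray | BinMap) -> pd.DataFrame:
    """Histogram of bin physical lengths in the standard size classes, with
    percentages to 2 decimals."""
    if isinstance(lengths_bp, BinMap):
        lengths_bp = lengths_bp.lengths_bp()
    lengths_bp = np.asarray(lengths_bp)
    total = lengths_bp.size
    rows = []
    for name, lo, hi in _LENGTH_CLASSES:
        n = int(((lengths_bp >= lo) & (lengths_bp < hi)).sum())
        pct = round(100.0 * n / total, 2) if total else 0.0
        rows.append((name, n, pct))
    return pd.DataFrame(rows, columns=["class", "count", "percent"])


def mean_breakpoints_per_line(n_breakpoints: int, n_lines: int) -> int:
    """Population-average breakpoint count per line, to the nearest integer."""
    return int(np.floor(n_breakpoints / n_lines + 0.5))
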