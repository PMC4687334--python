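"""Segregation-distortion scans and related population-composition tests.

In a doubled-haploid biparental population every marker is expected to
segregate 1:1.  Each marker is tested with the plain (no continuity
correction) one-degree-of-freedom chi-square

    chi2 = (n_P1 - n_P2)**2 / (n_P1 + n_P2)

at P = 0.01, deliberately without multiple-testing correction: linked
markers are not independent and the scan is descriptive, so the nominal
per-marker level is reported as-is.  Runs of consecutively distorted
markers sharing a direction form segregation-distortion regions (SDRs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binmap import A, B, BinMap

__all__ = [
    "scan_distortion",
    "envelope",
    "detect_sdrs",
    "line_composition",
    "compare_compositions",
    "distortion_qtl_orientation",
    "SDR",
]

CHI2_CRIT_P01 = float(stats.chi2.ppf(0.99, df=1))  # 6.6349


def _counts(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return (genotypes == A).sum(axis=0), (genotypes == B).sum(axis=0)


def scan_distortion(
    binmap_or_genotypes,
    marker_info: pd.DataFrame | None = None,
    alpha: float = 0.01,
    min_informative: int = 50,
) -> pd.DataFrame:
    """Per-marker distortion records.

    Returns a frame with marker_id, chrom, pos, n_p1, n_p2, p1_freq, chi2,
    tested, significant and direction ('towards_P1'/'towards_P2'/'none').
    Markers with fewer than ``min_informative`` non-missing lines are
    flagged untested (chi2 still reported).
    """
    if isinstance(binmap_or_genotypes, BinMap):
        genotypes = binmap_or_genotypes.genotypes
        marker_info = binmap_or_genotypes.bins[["marker_id", "chrom", "pos"]]
    else:
        genotypes = np.asarray(binmap_or_genotypes)
    n1, n2 = _counts(genotypes)
    total = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(total > 0, (n1 - n2) ** 2 / np.maximum(total, 1), np.nan)
        p1_freq = np.where(total > 0, n1 / np.maximum(total, 1), np.nan)
    crit = float(stats.chi2.ppf(1.0 - alpha, df=1))
    tested = total >= min_informative
    significant = tested & (chi2 > crit)
    direction = np.where(
        significant, np.where(n1 > n2, "towards_P1", "towards_P2"), "none"
    )
    out = pd.DataFrame(
        {
            "n_p1": n1,
            "n_p2": n2,
            "p1_freq": p1_freq,
            "chi2": chi2,
            "tested": tested,
            "significant": significant,
            "direction": direction,
        }
    )
    if marker_info is not None:
        out = pd.concat(
            [marker_info[["marker_id", "chrom", "pos"]].reset_index(drop=True), out], axis=1
        )
    return out


def envelope(n_lines: int, confidence: float = 0.99) -> tuple[float, float]:
    """Allele-frequency bounds under the no-distortion hypothesis:
    0.5 +/- z_(1+c)/2 * sqrt(0.25 / n)."""
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    z = float(stats.norm.ppf((1.0 + confidence) / 2.0))
    half = z * np.sqrt(0.25 / n_lines)
    return 0.5 - half, 0.5 + half


@dataclass(frozen=True)
class SDR:
    """Segregation-distortion region: a maximal run of same-direction
    significant markers in map order."""

    chrom: str
    start_marker: str
    end_marker: str
    start_pos: int
    end_pos: int
    peak_marker: str
    peak_chi2: float
    direction: str
    n_markers: int


def detect_sdrs(records: pd.DataFrame, min_run: int = 3) -> list[SDR]:
    """Maximal runs (length >= ``min_run``) of significant markers with a
    shared direction, within each chromosome in record order."""
    sdrs: list[SDR] = []
    for chrom, sub in records.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        k = 0
        n = len(sub)
        while k < n:
            d = sub.loc[k, "direction"]
            if d == "none":
                k += 1
                continue
            end = k
            while end + 1 < n and sub.loc[end + 1, "direction"] == d:
                end += 1
            if end - k + 1 >= min_run:
                run = sub.iloc[k : end + 1]
                peak = run.loc[run["chi2"].idxmax()]
                sdrs.append(
                    SDR(
                        chrom=str(chrom),
                        start_marker=str(run["marker_id"].iloc[0]),
                        end_marker=str(run["marker_id"].iloc[-1]),
                        start_pos=int(run["pos"].iloc[0]),
                        end_pos=int(run["pos"].iloc[-1]),
                        peak_marker=str(peak["marker_id"]),
                        peak_chi2=float(peak["chi2"]),
                        direction=str(d),
                        n_markers=len(run),
                    )
                )
            k = end + 1
    return sdrs


def line_composition(
    binmap_or_genotypes, line_ids: list[str] | None = None, alpha: float = 0.01
) -> pd.DataFrame:
    """Per-line parental genome composition and bias test.

    Percent of non-missing markers from each parent, with a chi-square test
    of the line's marker counts against 1:1 at level ``alpha``.
    """
    if isinstance(binmap_or_genotypes, BinMap):
        genotypes = binmap_or_genotypes.genotypes
        line_ids = binmap_or_genotypes.line_ids
    else:
        genotypes = np.asarray(binmap_or_genotypes)
    m1 = (genotypes == A).sum(axis=1)
    m2 = (genotypes == B).sum(axis=1)
    total = m1 + m2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(total > 0, (m1 - m2) ** 2 / np.maximum(total, 1), np.nan)
        pct1 = np.where(total > 0, 100.0 * m1 / np.maximum(total, 1), np.nan)
    crit = float(stats.chi2.ppf(1.0 - alpha, df=1))
    biased = chi2 > crit
    direction = np.where(biased, np.where(m1 > m2, "towards_P1", "towards_P2"), "none")
    return pd.DataFrame(
        {
            "line": line_ids if line_ids is not None else np.arange(len(m1)),
            "markers_p1": m1,
            "markers_p2": m2,
            "pct_p1": pct1,
            "chi2": chi2,
            "biased": biased,
            "direction": direction,
        }
    )


def compare_compositions(pct_p1_a: np.ndarray, pct_p1_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum comparison of per-line parent-1
    percentages between two populations.  Returns (statistic, p-value)."""
    res = stats.mannwhitneyu(pct_p1_a, pct_p1_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def distortion_qtl_orientation(
    sdrs: list[SDR],
    qtls: pd.DataFrame,
    records: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Relate SDR direction to the sign of overlapping QTL additive effects.

    ``qtls`` needs columns trait, chrom, bp_lo, bp_hi and ``a`` (additive
    effect of the parent-1 allele, +1 coding).  An overlapping pair is
    *concordant* when the distortion favors the parent whose allele
    decreases the trait (towards_P2 with a > 0, towards_P1 with a < 0).
    When per-marker ``records`` are given, a 2x2 chi-square of
    distorted-marker enrichment inside vs outside QTL intervals is added to
    the summary.
    """
    rows = []
    for _, q in qtls.iterrows():
        for sdr in sdrs:
            if sdr.chrom != q["chrom"]:
                continue
            if sdr.end_pos < q["bp_lo"] or sdr.start_pos > q["bp_hi"]:
                continue
            concordant = (sdr.direction == "towards_P2") == (q["a"] > 0)
            rows.append(
                (q["trait"], q["chrom"], q["bp_lo"], q["bp_hi"], float(q["a"]),
                 sdr.direction, bool(concordant))
            )
    table = pd.DataFrame(
        rows,
        columns=["trait", "chrom", "bp_lo", "bp_hi", "a", "sdr_direction", "concordant"],
    )
    summary: dict = {
        "n_overlaps": len(table),
        "n_concordant": int(table["concordant"].sum()) if len(table) else 0,
    }
    if records is not None and len(qtls):
        inside = np.zeros(len(records), dtype=bool)
        for _, q in qtls.iterrows():
            inside |= (
                (records["chrom"] == q["chrom"])
                & (records["pos"] >= q["bp_lo"])
                & (records["pos"] <= q["bp_hi"])
            ).to_numpy()
        sig = records["significant"].to_numpy()
        contingency = np.array(
            [
                [(sig & inside).sum(), (~sig & inside).sum()],
                [(sig & ~inside).sum(), (~sig & ~inside).sum()],
            ]
        )
        if contingency.min() >= 0 and contingency.sum(axis=1).min() > 0 and contingency.sum(axis=0).min() > 0:
            chi2, p, _, _ = stats.chi2_contingency(contingency, correction=False)
            summary["enrichment_chi2"] = float(chi2)
            summary["enrichment_p"] = float(p)
    return table, summary
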