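"""Shared tabular containers: parental SNP tables and read observations.

A *SNP table* is a pandas DataFrame with at least the columns
``snp_id, chrom, pos, allele_p1, allele_p2`` (``pos`` 1-based bp), one row per
polymorphic parental locus, sorted by (chrom, pos).

An :class:`ObservationMatrix` holds, per line x SNP, the counts of reads
supporting each parental allele.  It is dense in memory (int32) but is
serialized sparsely (only non-zero cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele_p1", "allele_p2"]

__all__ = ["SNP_COLUMNS", "validate_snp_table", "snp_table_from_genome", "ObservationMatrix"]


def validate_snp_table(snps: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SNP_COLUMNS if c not in snps.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    if snps["pos"].lt(1).any():
        raise ValueError("SNP positions must be 1-based (>= 1)")
    dup = snps.duplicated(subset=["chrom", "pos"])
    if dup.any():
        rows = snps.loc[dup, ["chrom", "pos"]].head(10).to_records(index=False)
        raise ValueError(f"duplicate (chrom, pos) entries: {list(rows)}")
    out = snps.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def snp_table_from_genome(genome, alleles=("A", "G")) -> pd.DataFrame:
    """SNP table at the genome's declared SNP positions (parent 1 carries
    ``alleles[0]`` everywhere; allele identity is immaterial downstream)."""
    frames = []
    for chrom in genome.chromosomes:
        pos = genome.snp_positions.get(chrom.name)
        if pos is None or pos.size == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"{chrom.name}_{p}" for p in pos],
                    "chrom": chrom.name,
                    "pos": pos,
                    "allele_p1": alleles[0],
                    "allele_p2": alleles[1],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=SNP_COLUMNS)
    return validate_snp_table(pd.concat(frames, ignore_index=True))


@dataclass
class ObservationMatrix:
    """Per-line, per-SNP parental-allele read counts.

    ``n_p1``/``n_p2`` are (n_lines, n_snps) arrays aligned with ``line_ids``
    and the rows of ``snps``.
    """

    line_ids: list[str]
    snps: pd.DataFrame
    n_p1: np.ndarray
    n_p2: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.line_ids), len(self.snps))
        if self.n_p1.shape != shape or self.n_p2.shape != shape:
            raise ValueError(f"count arrays must have shape {shape}")
        if (self.n_p1 < 0).any() or (self.n_p2 < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def total_reads(self) -> int:
        return int(self.n_p1.sum() + self.n_p2.sum())

    def reindex_snps(self, snps: pd.DataFrame) -> "ObservationMatrix":
        """Align columns to another SNP table carrying the same snp_ids
        (possibly re-ordered or with re-assigned coordinates)."""
        lookup = pd.Index(self.snps["snp_id"])
        idx = lookup.get_indexer(snps["snp_id"])
        if (idx < 0).any():
            raise ValueError("reindex_snps: unknown snp_id(s)")
        return ObservationMatrix(
            self.line_ids, snps.reset_index(drop=True), self.n_p1[:, idx], self.n_p2[:, idx]
        )

    # -- sparse TSV round-trip ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        li, si = np.nonzero(self.n_p1 + self.n_p2)
        return pd.DataFrame(
            {
                "line": np.asarray(self.line_ids, dtype=object)[li],
                "snp_id": self.snps["snp_id"].to_numpy()[si],
                "n_reads_p1": self.n_p1[li, si],
                "n_reads_p2": self.n_p2[li, si],
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, line_ids: list[str], snps: pd.DataFrame
    ) -> "ObservationMatrix":
        shape = (len(line_ids), len(snps))
        n1 = np.zeros(shape, dtype=np.int32)
        n2 = np.zeros(shape, dtype=np.int32)
        li = pd.Index(line_ids).get_indexer(frame["line"])
        si = pd.Index(snps["snp_id"]).get_indexer(frame["snp_id"])
        if (li < 0).any() or (si < 0).any():
            raise ValueError("observation frame refers to unknown line or SNP")
        n1[li, si] = frame["n_reads_p1"]
        n2[li, si] = frame["n_reads_p2"]
        return cls(list(line_ids), snps.reset_index(drop=True), n1, n2)
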