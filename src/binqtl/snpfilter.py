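"""Candidate-SNP retention filters for the parental SNP table.

A candidate between the two parents is retained when all of the following
hold, evaluated in this order (a rejected SNP is attributed to the FIRST
failing rule): read depth within [5, 100]; average mappable sites < 1.5;
novel-allele quality >= 20; homozygous in both parents and polymorphic
between them; uniquely placed (one alignment); and not within < 5 bp of any
other candidate.  The adjacency rule removes *both* members of a close pair
and is applied against all candidates, not only retained ones.

Optional columns (depth, avg_mappable_sites, novel_allele_quality,
zygosity, n_alignments) that are absent skip their rule with a warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tables import SNP_COLUMNS

logger = logging.getLogger(__name__)

__all__ = ["filter_candidates", "RULE_ORDER"]

RULE_ORDER = ["depth", "mappability", "quality", "zygosity", "uniqueness", "adjacency"]

DEPTH_MIN, DEPTH_MAX = 5, 100
MAPPABLE_MAX = 1.5
QUALITY_MIN = 20.0
ADJACENCY_BP = 5


def _rule_masks(c: pd.DataFrame) -> dict[str, np.ndarray]:
    """Failure mask per rule; missing optional columns yield all-pass."""
    n = len(c)
    masks: dict[str, np.ndarray] = {}

    def optional(col: str, fail) -> np.ndarray:
        if col not in c.columns:
            logger.warning("column %r absent: skipping its retention rule", col)
            return np.zeros(n, dtype=bool)
        return fail(c[col]).to_numpy()

    masks["depth"] = optional("depth", lambda s: (s < DEPTH_MIN) | (s > DEPTH_MAX))
    masks["mappability"] = optional("avg_mappable_sites", lambda s: s >= MAPPABLE_MAX)
    masks["quality"] = optional("novel_allele_quality", lambda s: s < QUALITY_MIN)
    zyg = optional("zygosity", lambda s: s != "hom")
    masks["zygosity"] = zyg | (c["allele_p1"] == c["allele_p2"]).to_numpy()
    masks["uniqueness"] = optional("n_alignments", lambda s: s != 1)

    adj = np.zeros(n, dtype=bool)
    for _chrom, sub in c.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        gaps = np.diff(pos)
        close = gaps < ADJACENCY_BP
        idx = sub.index.to_numpy()
        adj[idx[:-1][close]] = True
        adj[idx[1:][close]] = True
    masks["adjacency"] = adj
    return masks


def filter_candidates(candidates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the retention rules.

    Returns ``(retained, report)``: the retained SNP table (sorted by chrom,
    pos) and a per-rule rejection report with counts, each rejection
    attributed to the first failing rule in :data:`RULE_ORDER`.
    """
    missing = [col for col in SNP_COLUMNS if col not in candidates.columns]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    c = candidates.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    dup = c.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        names = c.loc[dup, "snp_id"].tolist()
        raise ValueError(f"duplicate (chrom, pos) candidates: {names[:20]}")
    if c.empty:
        report = pd.DataFrame({"reason": RULE_ORDER, "count": 0})
        return c, report

    masks = _rule_masks(c)
    reason = np.full(len(c), "", dtype=object)
    for rule in RULE_ORDER:
        hit = masks[rule] & (reason == "")
        reason[hit] = rule
    retained = c[reason == ""].reset_index(drop=True)
    report = pd.DataFrame(
        {"reason": RULE_ORDER, "count": [int((reason == r).sum()) for r in RULE_ORDER]}
    )
    return retained, report
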