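"""Two-point linkage analysis, grouping, marker ordering and cM maps.

Designed for doubled-haploid / recombinant-inbred coded genotype matrices
(codes from :mod:`binqtl.binmap`): the recombination fraction between two
markers is the discordance fraction over lines with both genotypes observed,
heterozygous calls being treated as missing.  Grouping is single-linkage on
the two-point LOD graph; ordering uses a minimum-spanning-tree backbone
followed by 2-opt improvement of the total adjacent recombination distance;
map distances come from the Kosambi map function summed over adjacent pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, connected_components, minimum_spanning_tree

from .binmap import BinMap

__all__ = [
    "pairwise_rf",
    "rf_matrices",
    "group_markers",
    "order_markers",
    "kosambi",
    "kosambi_inv",
    "LinkageMap",
    "build_map",
    "mean_spacing",
    "recrate_profile",
]

_LOG10_2 = np.log10(2.0)


def _signed_codes(genotypes: np.ndarray) -> np.ndarray:
    """A -> +1, B -> -1, H/U -> 0 (missing)."""
    x = np.zeros(genotypes.shape, dtype=np.float64)
    x[genotypes == 0] = 1.0
    x[genotypes == 1] = -1.0
    return x


def _rf_lod_from_counts(k: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n > 0, k / n, np.nan)
        # LOD at the untruncated MLE, with the 0*log(0) = 0 convention.
        t1 = np.where(k > 0, k * np.log10(np.where(k > 0, r, 1.0)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log10(np.where(n - k > 0, 1.0 - r, 1.0)), 0.0)
    lod = t1 + t2 + n * _LOG10_2
    eps = np.where(n > 0, 1.0 / (2.0 * np.maximum(n, 1)), np.nan)
    r_trunc = np.clip(r, eps, 0.5)
    return r_trunc, lod


def pairwise_rf(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """Recombination fraction and two-point LOD between two marker columns.

    Returns (r, lod); r is truncated to [1/(2n), 0.5].  Raises if fewer than
    two lines are informative for both markers.
    """
    x1, x2 = _signed_codes(np.asarray(g1)), _signed_codes(np.asarray(g2))
    both = (x1 != 0) & (x2 != 0)
    n = int(both.sum())
    if n < 2:
        raise ValueError(f"only {n} lines informative for both markers (need >= 2)")
    k = int((x1[both] != x2[both]).sum())
    r, lod = _rf_lod_from_counts(np.array(k), np.array(n))
    return float(r), float(lod)


def rf_matrices(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs (R, LOD, N) matrices for a lines x markers code matrix."""
    x = _signed_codes(genotypes)
    present = (x != 0).astype(np.float64)
    n = present.T @ present
    s = x.T @ x  # concordant minus discordant
    k = (n - s) / 2.0
    r, lod = _rf_lod_from_counts(k, n)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(lod, 0.0)
    return r, lod, n


def group_markers(lod: np.ndarray, lod_threshold: float = 9.0) -> np.ndarray:
    """Single-linkage connected components of the LOD >= threshold graph.

    Returns integer labels, relabelled so group 0 is the largest.
    """
    adj = csr_matrix(np.where(lod >= lod_threshold, 1.0, 0.0))
    _n, labels = connected_components(adj, directed=False)
    order = pd.Series(labels).value_counts().index.to_numpy()
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[v] for v in labels])


def _mst_backbone_order(dist: np.ndarray) -> np.ndarray:
    """Initial order: DFS preorder of the MST from a diameter endpoint."""
    m = dist.shape[0]
    if m <= 2:
        return np.arange(m)
    tree = minimum_spanning_tree(csr_matrix(dist))
    sym = tree + tree.T
    # farthest node from 0, then DFS preorder from there
    order0, _ = breadth_first_order(sym, 0, directed=False)
    start = int(order0[-1])
    seen = np.zeros(m, dtype=bool)
    out: list[int] = []
    indptr, indices = sym.indptr, sym.indices
    stack = [start]
    while stack:
        v = stack.pop()
        if seen[v]:
            continue
        seen[v] = True
        out.append(v)
        nbrs = indices[indptr[v] : indptr[v + 1]]
        # visit nearest neighbour last so DFS follows the cheapest edge first
        stack.extend(nbrs[np.argsort(-dist[v, nbrs])])
    return np.array(out)


def _two_opt(order: np.ndarray, dist: np.ndarray, max_sweeps: int = 40) -> np.ndarray:
    """2-opt on the open path (free endpoints via a zero-cost sentinel)."""
    m = len(order)
    if m < 4:
        return order
    aug = np.zeros((m + 1, m + 1))
    aug[:m, :m] = dist
    tour = np.concatenate((order, [m]))  # cycle through sentinel m
    big = m + 1
    for _sweep in range(max_sweeps):
        improved = False
        for i in range(1, big - 1):
            a, b = tour[i - 1], tour[i]
            j = np.arange(i + 1, big)
            c = tour[j]
            d = tour[(j + 1) % big]
            delta = aug[a, c] + aug[b, d] - aug[a, b] - aug[c, d]
            kbest = int(np.argmin(delta))
            if delta[kbest] < -1e-12:
                jj = i + 1 + kbest
                tour[i : jj + 1] = tour[i : jj + 1][::-1]
                improved = True
        if not improved:
            break
    cut = int(np.flatnonzero(tour == m)[0])
    path = np.concatenate((tour[cut + 1 :], tour[:cut]))
    return path


def order_markers(
    rf: np.ndarray,
    physical_pos: np.ndarray | None = None,
    max_sweeps: int = 40,
) -> np.ndarray:
    """Order markers of one linkage group.

    Minimizes total adjacent recombination distance via an MST backbone plus
    2-opt local improvement; the orientation (a global reversal is always
    equivalent) is fixed to ascending physical position when available.
    """
    m = rf.shape[0]
    if m < 2:
        return np.arange(m)
    order = _mst_backbone_order(rf)
    order = _two_opt(order, rf, max_sweeps=max_sweeps)
    if physical_pos is not None and m > 1:
        ranks = np.argsort(np.argsort(physical_pos[order]))
        if np.corrcoef(ranks, np.arange(m))[0, 1] < 0:
            order = order[::-1]
    return order


def kosambi(r) -> np.ndarray | float:
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r))."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr >= 0.5):
        raise ValueError("recombination fraction must satisfy 0 <= r < 0.5")
    d = 50.0 * np.arctanh(2.0 * r_arr)
    return float(d) if np.isscalar(r) else d


def kosambi_inv(d) -> np.ndarray | float:
    """Inverse Kosambi: r = tanh(d/50) / 2 for d in cM."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(d_arr / 50.0)
    return float(r) if np.isscalar(d) else r


@dataclass
class LinkageMap:
    """Ordered markers with linkage group and cM positions.

    ``markers`` columns: marker_id, group, order, cm, chrom, pos, r_next,
    lod_next (r_next/lod_next refer to the following marker in the group and
    are NaN on the last marker of each group).
    """

    markers: pd.DataFrame

    @property
    def n_groups(self) -> int:
        return int(self.markers["group"].nunique())

    @property
    def group_lengths(self) -> pd.Series:
        return self.markers.groupby("group")["cm"].max()

    @property
    def total_cm(self) -> float:
        return float(self.group_lengths.sum())

    def mean_spacing_cm(self) -> float:
        return mean_spacing(self.total_cm, len(self.markers), self.n_groups)

    def scaled(self, factor: float) -> "LinkageMap":
        """New map with every genetic interval divided by ``factor``."""
        m = self.markers.copy()
        m["cm"] = m["cm"] / factor
        return LinkageMap(m)


def mean_spacing(total_cm: float, n_markers: int, n_groups: int) -> float:
    """Mean adjacent-marker spacing = total length / (markers - groups),
    reported to one decimal."""
    return round(total_cm / (n_markers - n_groups), 1)


_R_CAP = 0.49  # numerical guard: keeps Kosambi distances finite


def build_map(
    binmap_or_genotypes,
    marker_info: pd.DataFrame | None = None,
    lod_threshold: float = 9.0,
) -> LinkageMap:
    """Group, order and place markers on the observed cM scale.

    Accepts a :class:`BinMap` or a raw (lines x markers) code matrix plus a
    marker frame with columns marker_id, chrom, pos.
    """
    if isinstance(binmap_or_genotypes, BinMap):
        genotypes = binmap_or_genotypes.genotypes
        marker_info = binmap_or_genotypes.bins[["marker_id", "chrom", "pos"]]
    else:
        genotypes = np.asarray(binmap_or_genotypes)
        if marker_info is None:
            raise ValueError("marker_info required with a raw genotype matrix")
    r, lod, _n = rf_matrices(genotypes)
    labels = group_markers(lod, lod_threshold)
    pos = marker_info["pos"].to_numpy(dtype=float)
    frames = []
    for g in range(labels.max() + 1):
        idx = np.flatnonzero(labels == g)
        sub_r = r[np.ix_(idx, idx)]
        order = order_markers(sub_r, physical_pos=pos[idx])
        ordered = idx[order]
        if len(ordered) > 1:
            r_adj = np.minimum(r[ordered[:-1], ordered[1:]], _R_CAP)
            lod_adj = lod[ordered[:-1], ordered[1:]]
            cm = np.concatenate(([0.0], np.cumsum(kosambi(r_adj))))
            r_next = np.concatenate((r_adj, [np.nan]))
            lod_next = np.concatenate((lod_adj, [np.nan]))
        else:
            cm = np.array([0.0])
            r_next = np.array([np.nan])
            lod_next = np.array([np.nan])
        sub = marker_info.iloc[ordered][["marker_id", "chrom", "pos"]].reset_index(drop=True)
        sub.insert(1, "group", g)
        sub.insert(2, "order", np.arange(len(ordered)))
        sub.insert(3, "cm", cm)
        sub["r_next"] = r_next
        sub["lod_next"] = lod_next
        frames.append(sub)
    markers = pd.concat(frames, ignore_index=True)
    return LinkageMap(markers)


def recrate_profile(map_: LinkageMap) -> pd.DataFrame:
    """Per adjacent-marker-interval recombination rate in cM/Mb.

    Rate is NaN (flagged) where the physical distance is zero.
    """
    rows = []
    for g, sub in map_.markers.groupby("group"):
        sub = sub.sort_values("order")
        cm = sub["cm"].to_numpy()
        bp = sub["pos"].to_numpy(dtype=float)
        for k in range(len(sub) - 1):
            d_cm = cm[k + 1] - cm[k]
            d_mb = abs(bp[k + 1] - bp[k]) / 1e6
            rate = d_cm / d_mb if d_mb > 0 else np.nan
            rows.append(
                (g, sub["marker_id"].iloc[k], sub["marker_id"].iloc[k + 1],
                 sub["chrom"].iloc[k], (bp[k] + bp[k + 1]) / 2, d_cm, d_mb, rate)
            )
    return pd.DataFrame(
        rows,
        columns=["group", "marker_a", "marker_b", "chrom", "mid_bp", "d_cm", "d_mb", "cm_per_mb"],
    )
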