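"""Composite interval mapping (CIM) for doubled-haploid / RIL populations.

The scan regresses the phenotype on the Haley-Knott conditional expectation
of the QTL genotype given flanking markers, with background marker
cofactors chosen by forward/backward stepwise regression (up to 10) and
excluded within a window (default +/- 5 cM) of the test position.  The test
statistic is LOD = (n/2) log10(RSS0 / RSS1), RSS0 being the cofactor-only
fit.  Peaks above the LOD threshold become QTL records with additive
effects (parent-1 allele coded +1), marginal R^2 and 2-LOD support
intervals mapped to physical coordinates through the marker map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linkmap import LinkageMap, kosambi_inv

__all__ = ["ScanSettings", "expected_genotype", "select_cofactors", "cim_scan", "qtl_summary"]


@dataclass(frozen=True)
class ScanSettings:
    step_cm: float = 0.5
    window_cm: float = 5.0
    max_cofactors: int = 10
    lod_threshold: float = 2.5
    support_drop: float = 2.0
    lod_cap: float = 50.0
    # Family-wise stepwise levels: per-candidate thresholds are these values
    # divided by the number of candidate markers (Bonferroni), so background
    # cofactors are only recruited on genome-wide evidence and a null scan
    # stays calibrated.
    f_enter_p: float = 0.01
    f_remove_p: float = 0.02

    def __post_init__(self) -> None:
        if self.step_cm <= 0:
            raise ValueError("step_cm must be > 0")
        if self.window_cm < 0:
            raise ValueError("window_cm must be >= 0")
        if self.max_cofactors < 0:
            raise ValueError("max_cofactors must be >= 0")


def _signed(genotypes: np.ndarray) -> np.ndarray:
    x = np.zeros(genotypes.shape, dtype=np.float64)
    x[genotypes == 0] = 1.0
    x[genotypes == 1] = -1.0
    return x


def expected_genotype(
    position_cm: float,
    marker_cm: np.ndarray,
    marker_x: np.ndarray,
) -> np.ndarray:
    """Haley-Knott expectation of the coded genotype at ``position_cm``.

    ``marker_cm`` is the ordered cM positions of a linkage group's markers
    and ``marker_x`` the lines x markers signed genotypes (+1 P1, -1 P2,
    0 missing).  Uses the immediate flanking markers per line under
    no-interference DH transmission with recombination fractions from the
    inverse Kosambi function; one missing flank falls back to single-marker
    decay, both missing give 0 (uninformative).
    """
    m = len(marker_cm)
    right = int(np.searchsorted(marker_cm, position_cm, side="left"))
    if right < m and abs(marker_cm[right] - position_cm) < 1e-9:
        at = marker_x[:, right]
        if right > 0 or right < m:  # observed genotype at a marker is exact
            out = at.astype(float).copy()
            missing = at == 0
            if missing.any():
                out[missing] = _flank_expectation(position_cm, marker_cm, marker_x, right - 1,
                                                  right + 1)[missing]
            return out
    return _flank_expectation(position_cm, marker_cm, marker_x, right - 1, right)


def _flank_expectation(p, marker_cm, marker_x, left, right) -> np.ndarray:
    m = len(marker_cm)
    n = marker_x.shape[0]
    has_l = left >= 0
    has_r = right < m
    xl = marker_x[:, left] if has_l else np.zeros(n)
    xr = marker_x[:, right] if has_r else np.zeros(n)
    r1 = kosambi_inv(max(p - marker_cm[left], 0.0)) if has_l else 0.5
    r2 = kosambi_inv(max(marker_cm[right] - p, 0.0)) if has_r else 0.5
    r12 = r1 * (1 - r2) + (1 - r1) * r2  # no-interference composition
    out = np.zeros(n)
    both = (xl != 0) & (xr != 0)
    onlyl = (xl != 0) & ~both
    onlyr = (xr != 0) & ~both
    if both.any():
        same = xl[both] == xr[both]
        # P(QTL = flank parent | concordant flanks) and | discordant flanks
        e_same = ((1 - r1) * (1 - r2) - r1 * r2) / max(1.0 - r12, 1e-12)
        e_diff = ((1 - r1) * r2 - r1 * (1 - r2)) / max(r12, 1e-12)
        vals = np.where(same, xl[both] * e_same, xl[both] * e_diff)
        out[both] = vals
    out[onlyl] = xl[onlyl] * (1 - 2 * r1)
    out[onlyr] = xr[onlyr] * (1 - 2 * r2)
    return out


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    coef, res, rank, _sv = np.linalg.lstsq(design, y, rcond=None)
    if res.size:
        return float(res[0])
    return float(np.sum((y - design @ coef) ** 2))


def _partial_f_p(rss0: float, rss1: float, n: int, p_full: int) -> float:
    """p-value of the 1-df partial F test (model1 nested in model0 + 1 term)."""
    df2 = n - p_full
    if df2 <= 0 or rss1 <= 0:
        return 0.0
    f = (rss0 - rss1) / (rss1 / df2)
    return float(stats.f.sf(max(f, 0.0), 1, df2))


def select_cofactors(
    y: np.ndarray,
    markers_x: np.ndarray,
    marker_order: np.ndarray | None = None,
    settings: ScanSettings = ScanSettings(),
) -> list[int]:
    """Forward/backward stepwise selection of background cofactor markers.

    ``markers_x`` is lines x markers signed coding with missing values
    already imputed.  Ties are broken toward the lower ``marker_order``
    value (chromosome, then cM).  Returns column indices, capped at
    ``settings.max_cofactors``.
    """
    y = np.asarray(y, dtype=float)
    n, m = markers_x.shape
    if settings.max_cofactors == 0 or np.allclose(y, y[0]):
        return []
    if n <= settings.max_cofactors + 2:
        raise ValueError("too few lines for the requested number of cofactors")
    rank = np.arange(m) if marker_order is None else np.asarray(marker_order)
    enter_p = settings.f_enter_p / m
    remove_p = settings.f_remove_p / m
    selected: list[int] = []
    ones = np.ones((n, 1))
    while len(selected) < settings.max_cofactors:
        base = np.hstack([ones, markers_x[:, selected]]) if selected else ones
        rss0 = _rss(base, y)
        best, best_key = None, None
        for j in range(m):
            if j in selected:
                continue
            rss1 = _rss(np.hstack([base, markers_x[:, [j]]]), y)
            p = _partial_f_p(rss0, rss1, n, base.shape[1] + 1)
            key = (p, rank[j])
            if best_key is None or key < best_key:
                best, best_key = j, key
        if best is None or best_key[0] >= enter_p:
            break
        selected.append(best)
        # backward elimination
        changed = True
        while changed and len(selected) > 1:
            changed = False
            full = np.hstack([ones, markers_x[:, selected]])
            rss_full = _rss(full, y)
            worst, worst_key = None, None
            for k, j in enumerate(selected):
                rest = [s for s in selected if s != j]
                rss_r = _rss(np.hstack([ones, markers_x[:, rest]]), y)
                p = _partial_f_p(rss_r, rss_full, n, full.shape[1])
                key = (-p, -rank[j])
                if worst_key is None or key < worst_key:
                    worst, worst_key = j, key
            if worst is not None and -worst_key[0] > remove_p:
                selected.remove(worst)
                changed = True
    # swap refinement: replace cofactors by better substitutes at equal
    # model size (no significance gate needed), re-centering a cofactor
    # that locked onto a flank of the signal it tags
    for _pass in range(5):
        swapped = False
        for k, j in enumerate(list(selected)):
            rest = [s for s in selected if s != j]
            base = np.hstack([ones, markers_x[:, rest]]) if rest else ones
            best_j, best_rss = j, _rss(np.hstack([base, markers_x[:, [j]]]), y)
            for cand in range(m):
                if cand in selected:
                    continue
                rss = _rss(np.hstack([base, markers_x[:, [cand]]]), y)
                if rss < best_rss - 1e-10:
                    best_j, best_rss = cand, rss
            if best_j != j:
                selected[selected.index(j)] = best_j
                swapped = True
        if not swapped:
            break
    return sorted(selected)


def _impute(x: np.ndarray) -> np.ndarray:
    """Replace missing (0) codes by the column mean of observed codes."""
    out = x.copy()
    for j in range(x.shape[1]):
        col = x[:, j]
        obs = col != 0
        if obs.any() and (~obs).any():
            out[~obs, j] = col[obs].mean()
    return out


def cim_scan(
    phenotype: np.ndarray,
    map_: LinkageMap,
    genotypes: np.ndarray,
    marker_ids: list[str] | None = None,
    settings: ScanSettings = ScanSettings(),
    trait: str = "trait",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genome-wide CIM scan.

    ``genotypes`` is the lines x markers code matrix the map was built from
    (columns matched to ``map_.markers`` by ``marker_ids``, defaulting to
    identical order).  Lines with missing (NaN) phenotype are dropped.
    Returns ``(profile, qtl_records)``.
    """
    y_all = np.asarray(phenotype, dtype=float)
    keep = ~np.isnan(y_all)
    y = y_all[keep]
    n = y.size
    if n < 30:
        raise ValueError("need >= 30 phenotyped lines")
    x_all = _signed(np.asarray(genotypes))[keep]

    mk = map_.markers
    if marker_ids is not None:
        col_of = {mid: k for k, mid in enumerate(marker_ids)}
        cols = np.array([col_of[mid] for mid in mk["marker_id"]])
    else:
        cols = np.arange(len(mk))
    # markers in map row order
    x_map = x_all[:, cols]
    x_imp = _impute(x_map)
    group = mk["group"].to_numpy()
    cm = mk["cm"].to_numpy(dtype=float)
    rank = np.lexsort((cm, group))
    order_rank = np.empty(len(mk))
    order_rank[rank] = np.arange(len(mk))

    cofactors = select_cofactors(y, x_imp, marker_order=order_rank, settings=settings)
    cof_group = group[cofactors]
    cof_cm = cm[cofactors]

    sst = float(np.sum((y - y.mean()) ** 2))
    ones = np.ones((n, 1))

    def lod_at(p: float, g_cm, g_x, base) -> tuple[float, float, float]:
        rss0 = _rss(base, y)
        xq = expected_genotype(p, g_cm, g_x)
        design1 = np.hstack([base, xq[:, None]])
        coef, res, _rank, _sv = np.linalg.lstsq(design1, y, rcond=None)
        rss1 = float(res[0]) if res.size else float(np.sum((y - design1 @ coef) ** 2))
        if rss1 <= 1e-12 * max(sst, 1.0):
            lod = settings.lod_cap
        else:
            lod = min((n / 2.0) * np.log10(rss0 / rss1), settings.lod_cap)
        return lod, float(coef[-1]), (rss0 - rss1) / sst if sst > 0 else 0.0

    def base_for(g, p: float) -> np.ndarray:
        near = (cof_group == g) & (np.abs(cof_cm - p) <= settings.window_cm)
        kept = [c for c, drop in zip(cofactors, near) if not drop]
        return np.hstack([ones, x_imp[:, kept]]) if kept else ones

    prof_rows = []
    group_arrays = {}
    for g in np.unique(group):
        gmask = group == g
        g_cm = cm[gmask]
        g_x = x_map[:, gmask]
        g_chrom = mk.loc[gmask, "chrom"].mode().iat[0]
        positions = np.arange(0.0, g_cm.max() + settings.step_cm / 2, settings.step_cm)
        group_arrays[g] = (g_cm, g_x, positions)
        for p in positions:
            lod, eff, r2 = lod_at(p, g_cm, g_x, base_for(g, p))
            prof_rows.append((g, g_chrom, p, lod, eff, r2))
    profile = pd.DataFrame(
        prof_rows, columns=["group", "chrom", "cm", "lod", "effect", "r2"]
    )

    # -- QTL records: peaks from the CIM profile; support intervals from the
    # peak-conditional profile (cofactor context frozen at the peak), a
    # profile-likelihood region not truncated by cofactor-window edges.
    rows = []
    for g, sub in profile.groupby("group"):
        sub = sub.sort_values("cm").reset_index(drop=True)
        lod = sub["lod"].to_numpy()
        cms = sub["cm"].to_numpy()
        above = lod >= settings.lod_threshold
        if not above.any():
            continue
        g_cm, g_x, positions = group_arrays[g]
        gmk = mk[mk["group"] == g].sort_values("order")
        mcm = gmk["cm"].to_numpy(dtype=float)
        mbp = gmk["pos"].to_numpy(dtype=float)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            seg = slice(s, e)
            k = s + int(np.argmax(lod[seg]))
            peak_lod = lod[k]
            base = base_for(g, cms[k])
            fixed = np.array([lod_at(p, g_cm, g_x, base)[0] for p in cms])
            thr = fixed[k] - settings.support_drop
            lo = k
            while lo > 0 and fixed[lo - 1] >= thr:
                lo -= 1
            hi = k
            while hi < len(fixed) - 1 and fixed[hi + 1] >= thr:
                hi += 1
            cm_lo = _interp_edge(cms, fixed, lo, thr, left=True)
            cm_hi = _interp_edge(cms, fixed, hi, thr, left=False)
            bp_lo, bp_hi = np.interp([cm_lo, cm_hi], mcm, mbp)
            rows.append(
                (trait, int(g), sub["chrom"].iat[0], cms[k], peak_lod,
                 sub["effect"].iat[k], 100.0 * sub["r2"].iat[k],
                 cm_lo, cm_hi, float(min(bp_lo, bp_hi)), float(max(bp_lo, bp_hi)))
            )
    records = pd.DataFrame(
        rows,
        columns=["trait", "group", "chrom", "peak_cm", "lod", "a", "r2_pct",
                 "cm_lo", "cm_hi", "bp_lo", "bp_hi"],
    )
    return profile, records


def _interp_edge(cms, lod, idx, thr, left: bool) -> float:
    """Linear interpolation of the support-interval endpoint between steps."""
    j = idx - 1 if left else idx + 1
    if j < 0 or j >= len(lod) or lod[j] >= thr:
        return float(cms[idx])
    frac = (lod[idx] - thr) / max(lod[idx] - lod[j], 1e-12)
    return float(cms[idx] + (cms[j] - cms[idx]) * frac)


_SIZE_CLASSES = [("<1Mb", 0.0, 1e6), ("1-5Mb", 1e6, 5e6), (">5Mb", 5e6, np.inf)]


def qtl_summary(records: pd.DataFrame, by: list[str] = ("trait",)) -> pd.DataFrame:
    """Per-group summary of QTL counts, LOD and R^2 ranges and support-
    interval lengths (cM and Mb, with physical size-class counts)."""
    if records.empty:
        return pd.DataFrame()
    rec = records.copy()
    rec["len_cm"] = rec["cm_hi"] - rec["cm_lo"]
    rec["len_mb"] = (rec["bp_hi"] - rec["bp_lo"]) / 1e6
    rows = []
    for key, sub in rec.groupby(list(by)):
        row = {
            k: v for k, v in zip(by, key if isinstance(key, tuple) else (key,))
        }
        row.update(
            n_qtl=len(sub),
            lod_min=sub["lod"].min(), lod_max=sub["lod"].max(),
            r2_min=sub["r2_pct"].min(), r2_max=sub["r2_pct"].max(),
            len_cm_mean=sub["len_cm"].mean(), len_cm_median=sub["len_cm"].median(),
            len_mb_mean=sub["len_mb"].mean(), len_mb_median=sub["len_mb"].median(),
        )
        for name, lo, hi in _SIZE_CLASSES:
            row[f"n_{name}"] = int(((sub["len_mb"] * 1e6 >= lo) & (sub["len_mb"] * 1e6 < hi)).sum())
        rows.append(row)
    return pd.DataFrame(rows)
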