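"""Composite interval mapping: genotype expectations, cofactors, scans."""

import math

import numpy as np
import pandas as pd
import pytest

from binqtl import BreedingScheme, GenomeSpec, QtlEffect, simulate_population
from binqtl.linkmap import build_map
from binqtl.qtl import ScanSettings, cim_scan, expected_genotype, select_cofactors


def _kosambi_cm(r):
    return 50.0 * math.atanh(2.0 * r)


class TestExpectedGenotype:
    def test_tight_flanks_near_one(self):
        cm = np.array([0.0, 0.2])
        x = np.array([[1.0, 1.0]])
        val = expected_genotype(0.1, cm, x)
        assert val[0] == pytest.approx(1.0, abs=1e-3)

    def test_midpoint_between_discordant_flanks_is_zero(self):
        cm = np.array([0.0, 20.0])
        x = np.array([[1.0, -1.0]])
        assert expected_genotype(10.0, cm, x)[0] == pytest.approx(0.0, abs=1e-12)

    def test_enumeration_oracle_concordant_flanks(self):
        """r1 = r2 = 0.1: value equals four-gamete-class enumeration."""
        r = 0.1
        d = _kosambi_cm(r)
        cm = np.array([0.0, 2 * d])
        x = np.array([[1.0, 1.0], [-1.0, -1.0], [1.0, -1.0], [-1.0, 1.0]])
        got = expected_genotype(d, cm, x)
        r12 = r * (1 - r) + (1 - r) * r
        e_same = ((1 - r) ** 2 - r**2) / (1 - r12)
        assert got[0] == pytest.approx(e_same, abs=1e-12)
        assert got[1] == pytest.approx(-e_same, abs=1e-12)
        assert got[2] == pytest.approx(0.0, abs=1e-12)

    def test_observed_marker_exact(self):
        cm = np.array([0.0, 5.0, 10.0])
        x = np.array([[1.0, -1.0, 1.0]])
        assert expected_genotype(5.0, cm, x)[0] == -1.0

    def test_single_flank_decay(self):
        r = 0.2
        d = _kosambi_cm(r)
        cm = np.array([0.0])
        x = np.array([[1.0]])
        assert expected_genotype(d, cm, x)[0] == pytest.approx(1 - 2 * r, abs=1e-12)

    def test_both_flanks_missing_zero(self):
        cm = np.array([0.0, 10.0])
        x = np.array([[0.0, 0.0]])
        assert expected_genotype(5.0, cm, x)[0] == 0.0


class TestCofactors:
    def test_max_zero_returns_empty(self, rng):
        y = rng.normal(0, 1, 100)
        x = rng.choice([-1.0, 1.0], size=(100, 20))
        assert select_cofactors(y, x, settings=ScanSettings(max_cofactors=0)) == []

    def test_constant_phenotype_empty(self, rng):
        x = rng.choice([-1.0, 1.0], size=(100, 20))
        assert select_cofactors(np.full(100, 3.3), x) == []

    def test_pure_noise_rarely_selects(self, rng):
        picks = 0
        for _ in range(10):
            y = rng.normal(0, 1, 150)
            x = rng.choice([-1.0, 1.0], size=(150, 50))
            picks += len(select_cofactors(y, x))
        assert picks <= 2

    def test_strong_qtls_recovered(self, rng):
        hits = 0
        for _ in range(10):
            x = rng.choice([-1.0, 1.0], size=(200, 60))
            truth = [5, 25, 45]
            y = x[:, truth] @ np.ones(3) + rng.normal(0, 1, 200)
            sel = select_cofactors(y, x)
            hits += all(t in sel for t in truth)
        assert hits >= 9


def _sim_marker_map(n_lines=194, seed=7, qtls=None, residual_sd=2.0, cm=50.0, n_mark=51):
    g = GenomeSpec.uniform([("c1", 20_000_000, cm)], snps_per_chrom=n_mark)
    pop = simulate_population(
        g, BreedingScheme(j=2, i=1, n_lines=n_lines), qtls=qtls,
        residual_sd=residual_sd, seed=seed,
    )
    codes, info = pop.marker_data()
    lmap = build_map(codes, info, lod_threshold=3.0)
    return pop, codes, lmap


class TestScan:
    def test_zero_cofactor_scan_matches_independent_oracle(self):
        """Simple-interval-mapping oracle (own Haley-Knott + closed-form OLS)
        agrees with the zero-cofactor scan to 1e-8 LOD."""
        pop, codes, lmap = _sim_marker_map(n_lines=150, seed=71, n_mark=50,
                                           qtls=[QtlEffect("c1", 9_000_000, 0.8)])
        y = pop.phenotypes["trait"]
        profile, _ = cim_scan(y, lmap, codes, settings=ScanSettings(max_cofactors=0))

        mk = lmap.markers.sort_values("order")
        mcm = mk["cm"].to_numpy()
        col = {m: k for k, m in enumerate(lmap.markers["marker_id"])}
        x_marker = np.where(codes == 0, 1.0, -1.0)[:, [col[m] for m in mk["marker_id"]]]
        n = len(y)
        sst = float(((y - y.mean()) ** 2).sum())

        def oracle_lod(p):
            # independent expectation: immediate flanks, Kosambi r, 4-class enumeration
            right = int(np.searchsorted(mcm, p, side="left"))
            if right < len(mcm) and abs(mcm[right] - p) < 1e-9:
                xq = x_marker[:, right]
            else:
                left = right - 1
                r1 = 0.5 * math.tanh((p - mcm[left]) / 50.0) if left >= 0 else 0.5
                r2 = 0.5 * math.tanh((mcm[right] - p) / 50.0) if right < len(mcm) else 0.5
                r12 = r1 * (1 - r2) + r2 * (1 - r1)
                xl = x_marker[:, left] if left >= 0 else np.zeros(n)
                xr = x_marker[:, right] if right < len(mcm) else np.zeros(n)
                e_same = ((1 - r1) * (1 - r2) - r1 * r2) / (1 - r12)
                e_diff = ((1 - r1) * r2 - r1 * (1 - r2)) / r12
                xq = np.where(xl == xr, xl * e_same, xl * e_diff)
            xc = xq - xq.mean()
            sxx = float((xc**2).sum())
            sxy = float((xc * (y - y.mean())).sum())
            rss1 = sst - (sxy**2 / sxx if sxx > 0 else 0.0)
            return (n / 2.0) * math.log10(sst / rss1)

        for _, row in profile.iloc[::7].iterrows():
            assert row["lod"] == pytest.approx(oracle_lod(row["cm"]), abs=1e-8)

    def test_lod_at_marker_equals_single_marker_regression(self):
        pop, codes, lmap = _sim_marker_map(n_lines=120, seed=72, n_mark=26,
                                           qtls=[QtlEffect("c1", 10_000_000, 1.0)])
        y = pop.phenotypes["trait"]
        profile, _ = cim_scan(y, lmap, codes, settings=ScanSettings(max_cofactors=0))
        mk = lmap.markers
        col = {m: k for k, m in enumerate(mk["marker_id"])}
        for _, m in mk.iloc[[5, 12, 20]].iterrows():
            at = profile[np.isclose(profile["cm"], round(m["cm"] * 2) / 2)]
            if at.empty or abs(at["cm"].iloc[0] - m["cm"]) > 1e-9:
                continue
            x = np.where(codes[:, col[m["marker_id"]]] == 0, 1.0, -1.0)
            n = len(y)
            sxy = float(((x - x.mean()) * (y - y.mean())).sum())
            sxx = float(((x - x.mean()) ** 2).sum())
            sst = float(((y - y.mean()) ** 2).sum())
            lod = (n / 2.0) * math.log10(sst / (sst - sxy**2 / sxx))
            assert at["lod"].iloc[0] == pytest.approx(lod, abs=1e-8)

    def test_noiseless_marker_phenotype_hits_lod_cap(self):
        pop, codes, lmap = _sim_marker_map(n_lines=100, seed=73, n_mark=26)
        col = 10
        y = np.where(codes[:, col] == 0, 1.0, -1.0)
        profile, _ = cim_scan(y, lmap, codes, settings=ScanSettings(max_cofactors=0))
        assert profile["lod"].max() == ScanSettings().lod_cap

    def test_requires_enough_lines(self):
        pop, codes, lmap = _sim_marker_map(n_lines=40, seed=74, n_mark=10)
        with pytest.raises(ValueError):
            cim_scan(np.ones(20) * np.nan, lmap, codes)

    def test_effect_estimate_unbiased(self):
        """Mean bias of the peak additive-effect estimate < 0.05*a."""
        effects = []
        rng = np.random.default_rng(75)
        for _ in range(80):
            pop, codes, lmap = _sim_marker_map(
                n_lines=194, seed=int(rng.integers(2**31)), n_mark=16, cm=30.0,
                qtls=[QtlEffect("c1", 10_000_000, 1.0)],
            )
            _prof, recs = cim_scan(pop.phenotypes["trait"], lmap, codes,
                                   settings=ScanSettings(max_cofactors=0))
            if len(recs):
                best = recs.loc[recs["lod"].idxmax()]
                effects.append(abs(best["a"]))
        assert len(effects) > 70
        assert abs(np.mean(effects) - 1.0) < 0.05

    def test_qtl_summary_shapes(self):
        from binqtl.qtl import qtl_summary

        recs = pd.DataFrame(
            {
                "trait": ["ft", "ft", "ph"],
                "group": 0, "chrom": "c1",
                "peak_cm": [10.0, 40.0, 5.0],
                "lod": [4.0, 6.0, 3.0],
                "a": [1.0, -0.5, 0.8],
                "r2_pct": [10.0, 15.0, 7.0],
                "cm_lo": [8, 35, 2], "cm_hi": [12, 44, 9],
                "bp_lo": [1e6, 2e6, 3e6], "bp_hi": [1.5e6, 8e6, 9.5e6],
            }
        )
        summary = qtl_summary(recs, by=["trait"]).set_index("trait")
        assert summary.loc["ft", "n_qtl"] == 2
        assert summary.loc["ft", "len_mb_median"] == pytest.approx((0.5 + 6) / 2)
        assert summary.loc["ph", "n_>5Mb"] == 1
        assert qtl_summary(pd.DataFrame()).empty
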