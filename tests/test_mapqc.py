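"""Misassembly QC, IBD SNP verification, integrated map, concordance."""

import numpy as np
import pandas as pd
import pytest

from binqtl import (
    BreedingScheme,
    GenomeSpec,
    simulate_observations,
    simulate_population,
    snp_table_from_genome,
)
from binqtl.binmap import A, B, U, BinMap, binmap_from_observations
from binqtl.mapqc import (
    build_integrated_map,
    concordance_tally,
    effective_sites,
    marker_density_windows,
    relocate_segment,
    scan_double_crossovers,
    verify_snps_ibd,
)


def make_binmap(geno, chrom="c1", grid=100_000):
    geno = np.asarray(geno, dtype=np.int8)
    n_bins = geno.shape[1]
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n_bins) * grid,
            "end": (np.arange(n_bins) + 1) * grid,
            "marker_id": [f"{chrom}.{k}" for k in range(n_bins)],
            "pos": np.arange(n_bins) * grid + grid // 2,
        }
    )
    return BinMap(bins=bins, genotypes=geno, line_ids=[f"L{k}" for k in range(len(geno))],
                  grid=grid)


class TestDxoScan:
    def test_clean_single_crossover_lines_not_flagged(self):
        rows = [[A] * k + [B] * (10 - k) for k in range(11)]
        prof = scan_double_crossovers(make_binmap(rows))
        assert prof.flagged == []
        assert prof.counts.sum() == 0

    def test_single_line_isolated_error_not_flagged(self):
        rows = [[A] * 10 for _ in range(30)]
        rows[0][5] = B  # one line, one bin
        prof = scan_double_crossovers(make_binmap(rows))
        assert prof.counts[5] == 1
        assert prof.flagged == []

    def test_population_wide_alien_block_flagged(self, rng):
        # 40 lines; bins 4-5 carry genotypes uncorrelated with their flanks
        geno = np.tile(np.where(rng.random(40) < 0.5, A, B)[:, None], (1, 12)).astype(np.int8)
        alien = np.where(rng.random(40) < 0.5, A, B).astype(np.int8)
        geno[:, 4] = alien
        geno[:, 5] = alien
        prof = scan_double_crossovers(make_binmap(geno))
        assert prof.flagged == [(4, 5)]

    def test_long_runs_not_double_crossovers(self):
        # middle segment spans 3 Mb > max_span: a genuine linked block
        rows = [[A] * 10 + [B] * 30 + [A] * 10 for _ in range(20)]
        prof = scan_double_crossovers(make_binmap(rows), max_span_bp=2_000_000)
        assert prof.flagged == []


class TestRelocate:
    def test_correctly_placed_segment_not_moved(self, rng):
        # smooth single-crossover map; force-relocate an arbitrary segment
        rows = [[A] * k + [B] * (20 - k) for k in rng.integers(0, 21, size=40)]
        bm = make_binmap(rows)
        res = relocate_segment(bm, (8, 9))
        assert res["dxo_after"] >= res["dxo_before"] or res["proposal_after"] == 7
        if res["accepted"]:
            assert res["proposal_after"] == 7  # re-inserted where it was

    def test_acceptance_requires_strict_reduction(self, rng):
        rows = [[A] * 20 for _ in range(10)]
        bm = make_binmap(rows)
        res = relocate_segment(bm, (5, 6))
        assert not res["accepted"]
        assert res["binmap"] is bm


class TestVerifySnps:
    @pytest.fixture()
    def pipeline(self):
        g = GenomeSpec.uniform([("c1", 5_000_000, 20.0)], snps_per_chrom=3000)
        pop = simulate_population(g, BreedingScheme(j=2, i=1, n_lines=60), seed=81)
        snps = snp_table_from_genome(g)
        obs = simulate_observations(pop, snps, coverage=0.5, error_rate=0.0, seed=82)
        bm = binmap_from_observations(obs, chrom_lengths={"c1": 5_000_000})
        return snps, obs, bm

    def test_error_free_data_all_verified(self, pipeline):
        snps, obs, bm = pipeline
        tally, retained = verify_snps_ibd(snps, obs, bm)
        covered = tally[(tally["verified"] + tally["contradicted"]) > 0]
        # SNPs on the far side of a within-bin crossover contradict the bin
        # consensus even with perfect reads; everything else verifies cleanly
        assert (covered["contradicted"] == 0).mean() > 0.95
        assert (covered["verified"] >= 1).all()
        assert tally["contradicted"].sum() / tally["verified"].sum() < 0.01
        assert len(retained) == (tally["status"] == "retained").sum()

    def test_conservation_identity(self, pipeline):
        """verified + contradicted == informative observations in A/B bins."""
        snps, obs, bm = pipeline
        tally, _ = verify_snps_ibd(snps, obs, bm)
        observed_call = np.where(obs.n_p1 > obs.n_p2, A, np.where(obs.n_p2 > obs.n_p1, B, U))
        # expected genotype per line x SNP from the containing bin
        starts = bm.bins["start"].to_numpy()
        k = np.searchsorted(starts, snps["pos"].to_numpy() - 1, side="right") - 1
        expected = bm.genotypes[:, k]
        informative = (observed_call != U) & ((expected == A) | (expected == B))
        assert (tally["verified"] + tally["contradicted"]).sum() == informative.sum()

    def test_retention_bookkeeping(self, pipeline):
        snps, obs, bm = pipeline
        tally, retained = verify_snps_ibd(snps, obs, bm)
        excluded = (tally["status"] == "excluded").sum()
        assert len(retained) + excluded == len(snps)

    def test_strict_mode_excludes_contradicted(self, pipeline):
        snps, obs, bm = pipeline
        # inject contradictions by flipping some observations
        obs.n_p1[:, 100], obs.n_p2[:, 100] = obs.n_p2[:, 100].copy(), obs.n_p1[:, 100].copy()
        lax, _ = verify_snps_ibd(snps, obs, bm, exclude_contradicted=False)
        strict, _ = verify_snps_ibd(snps, obs, bm, exclude_contradicted=True)
        row_lax = lax.iloc[100]
        row_strict = strict.iloc[100]
        assert row_strict["contradicted"] > 0
        assert row_strict["status"] == "excluded"
        assert row_lax["status"] == ("retained" if row_lax["verified"] >= 1 else "excluded")


class TestIntegratedMap:
    def test_window_counts(self):
        sets = {
            "traditional": pd.DataFrame(
                {"marker_id": ["ssr1", "ssr2"], "chrom": "c1", "pos": [2_000_000, 15_000_000]}
            ),
            "bin": pd.DataFrame({"marker_id": ["b1"], "chrom": "c1", "pos": [9_000_000]}),
            "snp": pd.DataFrame(
                {"marker_id": [f"s{k}" for k in range(5)], "chrom": "c1",
                 "pos": [1e6, 2e6, 3e6, 11e6, 12e6]}
            ),
        }
        merged = build_integrated_map(sets)
        win = marker_density_windows(merged, window_bp=10_000_000)
        first = win[win["window"] == 0].iloc[0]
        assert first["traditional"] == 1 and first["bin"] == 1 and first["snp"] == 3
        assert win[win["window"] == 1].iloc[0]["snp"] == 2
        # window counts sum to class totals
        assert win["snp"].sum() == 5

    def test_sorted_and_collision_flagged(self):
        sets = {
            "bin": pd.DataFrame({"marker_id": ["b"], "chrom": "c1", "pos": [500]}),
            "snp": pd.DataFrame({"marker_id": ["s"], "chrom": "c1", "pos": [500]}),
        }
        merged = build_integrated_map(sets)
        assert merged["collision"].all()
        sets2 = {k: v.iloc[::-1] for k, v in sets.items()}
        assert build_integrated_map(sets2)["marker_id"].tolist() == merged["marker_id"].tolist()


class TestConcordance:
    def test_effective_sites_arithmetic(self):
        assert effective_sites(1092, 44, 74) == 974

    def test_percent_with_het_and_missing(self):
        samples = [f"s{k}" for k in range(12)]
        markers = [f"m{k}" for k in range(91)]
        idx = [(s, m) for s in samples for m in markers]  # 1092 combinations
        rng = np.random.default_rng(0)
        order = rng.permutation(len(idx))
        geno_a = np.array(["A"] * len(idx), dtype=object)
        geno_b = geno_a.copy()
        missing = order[:44]
        het = order[44:118]
        discord = order[118 : 118 + 55]
        geno_a[missing] = None
        geno_b[het] = "H"
        geno_b[discord] = "G"
        a = pd.DataFrame({"sample": [i[0] for i in idx], "marker": [i[1] for i in idx],
                          "genotype": geno_a})
        b = pd.DataFrame({"sample": [i[0] for i in idx], "marker": [i[1] for i in idx],
                          "genotype": geno_b})
        out = concordance_tally(a, b)
        assert out["total"] == 1092
        assert out["missing"] == 44
        assert out["heterozygous"] == 74
        assert out["effective"] == 974
        assert out["consistent"] == 919
        assert out["percent"] == 94.4

    def test_identical_call_sets(self):
        a = pd.DataFrame({"sample": ["s"] * 3, "marker": ["m1", "m2", "m3"],
                          "genotype": ["A", "G", "A"]})
        out = concordance_tally(a, a.copy())
        assert out["percent"] == 100.0

    def test_disjoint_indices_error(self):
        a = pd.DataFrame({"sample": ["s1"], "marker": ["m1"], "genotype": ["A"]})
        b = pd.DataFrame({"sample": ["s2"], "marker": ["m2"], "genotype": ["A"]})
        with pytest.raises(ValueError):
            concordance_tally(a, b)
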