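"""Simulator invariants: meiosis, breeding scheme, selection, observations."""

import math

import numpy as np
import pandas as pd
import pytest

from binqtl import (
    BreedingScheme,
    GenomeSpec,
    QtlEffect,
    SelectedLocus,
    simulate_meiosis,
    simulate_observations,
    simulate_population,
    snp_table_from_genome,
)
from binqtl.genome import ConfigurationError


def _f1(length_bp):
    return {
        "c1": (
            (np.array([length_bp]), np.array([0], dtype=np.int8)),
            (np.array([length_bp]), np.array([1], dtype=np.int8)),
        )
    }


def _homozygote(length_bp, parent):
    hap = (np.array([length_bp]), np.array([parent], dtype=np.int8))
    return {"c1": (hap, hap)}


class TestMeiosis:
    def test_homozygous_parent_gives_identical_gamete(self):
        g = GenomeSpec.uniform([("c1", 1_000_000, 200.0)])
        rng = np.random.default_rng(0)
        for _ in range(20):
            gam = simulate_meiosis(_homozygote(1_000_000, 1), g, rng)
            ends, parents = gam["c1"]
            assert ends.tolist() == [1_000_000]
            assert parents.tolist() == [1]

    def test_same_seed_bit_identical(self):
        g = GenomeSpec.uniform([("c1", 5_000_000, 120.0)])
        g1 = simulate_meiosis(_f1(5_000_000), g, np.random.default_rng(7))
        g2 = simulate_meiosis(_f1(5_000_000), g, np.random.default_rng(7))
        assert np.array_equal(g1["c1"][0], g2["c1"][0])
        assert np.array_equal(g1["c1"][1], g2["c1"][1])

    def test_crossover_count_poisson_mean(self):
        """100-cM chromosome: one crossover per meiosis on average."""
        g = GenomeSpec.uniform([("c1", 10_000_000, 100.0)])
        rng = np.random.default_rng(1)
        n = 6000
        counts = np.array(
            [len(simulate_meiosis(_f1(10_000_000), g, rng)["c1"][0]) - 1 for _ in range(n)]
        )
        se = math.sqrt(1.0 / n)  # Poisson(1) mean variance 1
        assert abs(counts.mean() - 1.0) < 3 * se

    def test_gamete_tiles_chromosome(self):
        g = GenomeSpec.uniform([("c1", 2_000_000, 300.0)])
        rng = np.random.default_rng(3)
        for _ in range(50):
            ends, parents = simulate_meiosis(_f1(2_000_000), g, rng)["c1"]
            assert ends[-1] == 2_000_000
            assert np.all(np.diff(ends) > 0)
            assert np.all(parents[:-1] != parents[1:])  # canonical form


class TestPopulation:
    def test_segment_tiling_every_line(self, dh_population, small_genome):
        for ind in dh_population.haplotypes:
            for chrom in small_genome.chromosomes:
                for hap in ind[chrom.name]:
                    ends, _ = hap
                    assert ends[-1] == chrom.length_bp
                    assert np.all(np.diff(ends) > 0)

    def test_dh_lines_fully_homozygous(self, dh_population, small_genome):
        for chrom in small_genome.chromosomes:
            pos = small_genome.snp_positions[chrom.name]
            codes = dh_population.genotype_codes(chrom.name, pos)
            assert not (codes == 2).any()

    def test_mean_allele_frequency_half_without_selection(self, small_genome):
        pop = simulate_population(
            small_genome, BreedingScheme(j=2, i=1, n_lines=400), seed=5
        )
        fracs = []
        for chrom in small_genome.chromosomes:
            pos = small_genome.snp_positions[chrom.name]
            codes = pop.genotype_codes(chrom.name, pos)
            fracs.append((codes == 0).mean(axis=1))
        per_line = np.mean(fracs, axis=0)
        se = per_line.std(ddof=1) / math.sqrt(len(per_line))
        assert abs(per_line.mean() - 0.5) < 3 * se

    def test_selection_shifts_allele_frequency(self, small_genome):
        sel = [SelectedLocus("chr1", 5_000_000, fitness_p1=1.0, fitness_p2=0.5)]
        pop = simulate_population(
            small_genome, BreedingScheme(j=2, i=1, n_lines=300), selection=sel, seed=6
        )
        codes = pop.genotype_codes("chr1", np.array([5_000_000]))[:, 0]
        freq = (codes == 0).mean()
        # two gamete-selection rounds (F2 + DH): odds 4:1 for the P1 allele
        assert freq > 0.6

    def test_phenotypes_additive(self, small_genome):
        qtls = [QtlEffect("chr1", 5_000_000, a=2.0, trait="ht")]
        pop = simulate_population(
            small_genome, BreedingScheme(j=2, i=1, n_lines=400), qtls=qtls,
            residual_sd=0.5, seed=7,
        )
        x = np.where(pop.genotype_codes("chr1", np.array([5_000_000]))[:, 0] == 0, 1.0, -1.0)
        y = pop.phenotypes["ht"]
        gap = y[x > 0].mean() - y[x < 0].mean()
        assert abs(gap - 4.0) < 0.3  # 2a separation between genotype classes

    def test_breakpoints_match_expanded_map_length(self):
        """Mean junctions per DH line ~= expanded map length in Morgans."""
        g = GenomeSpec.uniform([("c1", 10_000_000, 100.0)])
        pop = simulate_population(g, BreedingScheme(j=12, i=1, n_lines=400), seed=8)
        bp = pop.breakpoint_counts()
        expected = 6.5 * 1.0  # alpha * F2 Morgans
        se = bp.std(ddof=1) / math.sqrt(len(bp))
        assert abs(bp.mean() - expected) < 3 * se + 0.15 * expected

    def test_too_few_lines_rejected(self, small_genome):
        with pytest.raises(ConfigurationError):
            BreedingScheme(j=2, i=1, n_lines=1)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ConfigurationError):
            BreedingScheme(j=1, i=1, n_lines=10)


@pytest.mark.parametrize(
    "j,i,final,alpha",
    [(2, math.inf, "SELF", 2.0), (6, math.inf, "SELF", 4.0)],
)
def test_expansion_recovery_selfed_schemes(j, i, final, alpha):
    """Adjacent-discordance map length over F2 length ~= alpha within 5%
    (dense error-free markers, large intermating census)."""
    from binqtl.linkmap import kosambi

    g = GenomeSpec.uniform([("c1", 10_000_000, 50.0)], snps_per_chrom=251)
    pop = simulate_population(
        g, BreedingScheme(j=j, i=i, n_lines=800, final_step=final, n_census=1600), seed=9
    )
    codes, _info = pop.marker_data()
    x = np.where(codes == 0, 1, np.where(codes == 1, -1, 0))
    both = (x[:, :-1] != 0) & (x[:, 1:] != 0)
    disc = ((x[:, :-1] != x[:, 1:]) & both).sum(axis=0) / both.sum(axis=0)
    est = kosambi(np.minimum(disc, 0.49)).sum() / 50.0
    assert est == pytest.approx(alpha, rel=0.05)


class TestObservations:
    def test_zero_coverage_empty(self, dh_population, small_genome):
        snps = snp_table_from_genome(small_genome)
        obs = simulate_observations(dh_population, snps, coverage=0.0, seed=1)
        assert obs.total_reads == 0
        assert obs.to_frame().empty

    def test_error_free_reads_match_truth(self, dh_population, small_genome):
        snps = snp_table_from_genome(small_genome)
        obs = simulate_observations(dh_population, snps, coverage=10.0, error_rate=0.0, seed=2)
        for chrom, sub in snps.groupby("chrom"):
            codes = dh_population.genotype_codes(str(chrom), sub["pos"].to_numpy())
            cols = sub.index.to_numpy()
            assert (obs.n_p2[:, cols][codes == 0] == 0).all()
            assert (obs.n_p1[:, cols][codes == 1] == 0).all()

    def test_total_reads_poisson(self, dh_population, small_genome):
        snps = snp_table_from_genome(small_genome)
        obs = simulate_observations(dh_population, snps, coverage=0.31, error_rate=0.01, seed=3)
        lam = 0.31 * dh_population.n_lines * len(snps)
        assert abs(obs.total_reads - lam) < 3 * math.sqrt(lam)

    def test_invalid_error_rate(self, dh_population, small_genome):
        snps = snp_table_from_genome(small_genome)
        with pytest.raises(ConfigurationError):
            simulate_observations(dh_population, snps, coverage=1.0, error_rate=0.6)

    def test_sparse_frame_round_trip(self, dh_population, small_genome):
        from binqtl.tables import ObservationMatrix

        snps = snp_table_from_genome(small_genome)
        obs = simulate_observations(dh_population, snps, coverage=0.31, error_rate=0.01, seed=4)
        back = ObservationMatrix.from_frame(obs.to_frame(), obs.line_ids, snps)
        assert np.array_equal(back.n_p1, obs.n_p1)
        assert np.array_equal(back.n_p2, obs.n_p2)


def test_segments_frame_round_trips_parentage(dh_population):
    frame = dh_population.segments_frame()
    assert set(frame.columns) == {"line", "chrom", "start", "end", "parent"}
    # 1-based inclusive segments tile each chromosome
    for (_line, _chrom), sub in frame.groupby(["line", "chrom"]):
        sub = sub.sort_values("start")
        assert sub["start"].iloc[0] == 1
        assert (sub["start"].iloc[1:].to_numpy() == sub["end"].iloc[:-1].to_numpy() + 1).all()
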