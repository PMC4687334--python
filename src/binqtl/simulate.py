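"""Forward-in-time simulation of intermated biparental breeding schemes.

The simulator tracks ancestry mosaics: each haplotype is a list of segments
(end positions + parental origin) tiling every chromosome.  Meiosis draws a
Poisson number of crossovers per chromosome (mean = F2 genetic length in
Morgans, no interference) with crossover positions uniform on the cM scale,
so genetic distances are faithful under any bp<->cM map.  Doubled-haploid
(DH) extraction samples one gamete per selected individual and doubles it.

Viability selection is applied by rejection sampling at the gamete or zygote
stage; additive QTL phenotypes are genotype-weighted sums plus Gaussian
noise.  All randomness flows from one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BreedingScheme, ConfigurationError, GenomeSpec, QtlEffect, SelectedLocus
from .tables import ObservationMatrix, validate_snp_table

__all__ = [
    "Haplotype",
    "simulate_meiosis",
    "simulate_population",
    "simulate_observations",
    "TruePopulation",
]

# A haplotype on one chromosome: (ends, parents).  Segment k covers the
# half-open physical interval [ends[k-1], ends[k]) in 0-based bp (ends[-1] is
# the chromosome length); parents[k] is 0 (parent 1) or 1 (parent 2).
Haplotype = tuple[np.ndarray, np.ndarray]

_MAX_SELF_GENERATIONS = 30  # i = inf in practice: residual heterozygosity 2^-30
_MAX_REJECTION_TRIES = 10_000


def _pure_hap(length_bp: int, parent: int) -> Haplotype:
    return (np.array([length_bp], dtype=np.int64), np.array([parent], dtype=np.int8))


def _canonical(ends: np.ndarray, parents: np.ndarray) -> Haplotype:
    """Drop empty segments and merge adjacent segments of equal origin."""
    starts = np.concatenate(([0], ends[:-1]))
    keep = ends > starts
    ends, parents = ends[keep], parents[keep]
    if parents.size > 1:
        last = np.concatenate((parents[:-1] != parents[1:], [True]))
        ends, parents = ends[last], parents[last]
    return ends, parents


def _splice(h1: Haplotype, h2: Haplotype, cuts: np.ndarray, first: int) -> Haplotype:
    """Gamete from two haplotypes switching source at each cut position."""
    length = int(h1[0][-1])
    if cuts.size == 0:
        src = (h1, h2)[first]
        return (src[0].copy(), src[1].copy())
    bounds = np.concatenate(([0], cuts, [length]))
    out_ends: list[np.ndarray] = []
    out_par: list[np.ndarray] = []
    src_idx = first
    for k in range(len(bounds) - 1):
        lo, hi = int(bounds[k]), int(bounds[k + 1])
        if hi <= lo:
            src_idx ^= 1
            continue
        ends, parents = (h1, h2)[src_idx]
        a = int(np.searchsorted(ends, lo, side="right"))
        b = int(np.searchsorted(ends, hi - 1, side="right"))
        seg_ends = ends[a : b + 1].copy()
        seg_ends[-1] = hi
        out_ends.append(seg_ends)
        out_par.append(parents[a : b + 1])
        src_idx ^= 1
    return _canonical(np.concatenate(out_ends), np.concatenate(out_par))


def _crossover_positions(genome: GenomeSpec, chrom, rng: np.random.Generator) -> np.ndarray:
    n_xo = rng.poisson(chrom.length_cm / 100.0)
    if n_xo == 0:
        return np.empty(0, dtype=np.int64)
    cm = rng.uniform(0.0, chrom.length_cm, size=n_xo)
    bp = np.unique(np.asarray(genome.bp_of_cm(chrom.name, cm)).round().astype(np.int64))
    return bp[(bp > 0) & (bp < chrom.length_bp)]


Individual = dict[str, tuple[Haplotype, Haplotype]]


def simulate_meiosis(parent: Individual, genome: GenomeSpec, rng: np.random.Generator) -> dict[str, Haplotype]:
    """One gamete from a diploid parent (all chromosomes, independent)."""
    gamete: dict[str, Haplotype] = {}
    for chrom in genome.chromosomes:
        h1, h2 = parent[chrom.name]
        if int(h1[0][-1]) != chrom.length_bp or int(h2[0][-1]) != chrom.length_bp:
            raise ConfigurationError(f"haplotypes do not tile chromosome {chrom.name}")
        cuts = _crossover_positions(genome, chrom, rng)
        gamete[chrom.name] = _splice(h1, h2, cuts, first=int(rng.integers(2)))
    return gamete


def _hap_allele(hap: Haplotype, chrom_pos0: int) -> int:
    ends, parents = hap
    return int(parents[int(np.searchsorted(ends, chrom_pos0, side="right"))])


def _gamete_fitness(gamete: dict[str, Haplotype], loci: list[SelectedLocus]) -> float:
    w = 1.0
    for loc in loci:
        allele = _hap_allele(gamete[loc.chrom], loc.pos_bp - 1)
        w *= loc.fitness_p1 if allele == 0 else loc.fitness_p2
    return w


def _zygote_fitness(ind: Individual, loci: list[SelectedLocus]) -> float:
    w = 1.0
    for loc in loci:
        for hap in ind[loc.chrom]:
            allele = _hap_allele(hap, loc.pos_bp - 1)
            w *= loc.fitness_p1 if allele == 0 else loc.fitness_p2
    return w


@dataclass
class TruePopulation:
    """Ground-truth population: per-line ancestry mosaics and phenotypes."""

    genome: GenomeSpec
    scheme: BreedingScheme
    line_ids: list[str]
    haplotypes: list[Individual]
    phenotypes: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def is_dh(self) -> bool:
        return self.scheme.final_step == "DH"

    def genotype_codes(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """(n_lines, len(positions)) int8 codes: 0 = P1/P1, 1 = P2/P2, 2 = het.
        ``positions`` are 1-based bp."""
        pos0 = np.asarray(positions, dtype=np.int64) - 1
        out = np.empty((self.n_lines, pos0.size), dtype=np.int8)
        for li, ind in enumerate(self.haplotypes):
            h1, h2 = ind[chrom]
            a = h1[1][np.searchsorted(h1[0], pos0, side="right")]
            b = h2[1][np.searchsorted(h2[0], pos0, side="right")]
            out[li] = np.where(a == b, a, 2)
        return out

    def junctions(self, line_index: int, chrom: str) -> np.ndarray:
        """True ancestry-switch positions (0-based bp ends) on the first
        haplotype of a line; for DH lines these are the line's crossovers."""
        ends, _parents = self.haplotypes[line_index][chrom][0]
        return ends[:-1].copy()

    def breakpoint_counts(self) -> np.ndarray:
        return np.array(
            [
                sum(self.junctions(li, c.name).size for c in self.genome.chromosomes)
                for li in range(self.n_lines)
            ]
        )

    def marker_data(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Error-free genotype codes at the genome's SNP positions.

        Returns (codes, marker_info): a lines x markers matrix (0/1/2) and a
        frame with marker_id, chrom, pos — the idealized full-observation
        data set used for map-theory experiments.
        """
        cols, rows = [], []
        for chrom in self.genome.chromosomes:
            pos = self.genome.snp_positions.get(chrom.name)
            if pos is None or pos.size == 0:
                continue
            cols.append(self.genotype_codes(chrom.name, pos))
            rows.extend((f"{chrom.name}_{p}", chrom.name, int(p)) for p in pos)
        codes = np.concatenate(cols, axis=1) if cols else np.empty((self.n_lines, 0), np.int8)
        info = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos"])
        return codes, info

    def segments_frame(self) -> pd.DataFrame:
        """Segments TSV layout: line, chrom, start, end (1-based inclusive), parent."""
        rows = []
        for lid, ind in zip(self.line_ids, self.haplotypes):
            for chrom in self.genome.chromosomes:
                ends, parents = ind[chrom.name][0]
                starts = np.concatenate(([0], ends[:-1]))
                for s, e, p in zip(starts, ends, parents):
                    rows.append((lid, chrom.name, int(s) + 1, int(e), "P1" if p == 0 else "P2"))
        return pd.DataFrame(rows, columns=["line", "chrom", "start", "end", "parent"])

    def phenotype_frame(self) -> pd.DataFrame:
        rows = [
            (lid, trait, float(vals[li]))
            for trait, vals in self.phenotypes.items()
            for li, lid in enumerate(self.line_ids)
        ]
        return pd.DataFrame(rows, columns=["line", "trait", "value"])


def _draw_offspring(
    parents: list[Individual],
    genome: GenomeSpec,
    rng: np.random.Generator,
    gamete_loci: list[SelectedLocus],
    zygote_loci: list[SelectedLocus],
) -> Individual:
    """One offspring by random pairing without selfing, with rejection-
    sampled viability selection."""
    n = len(parents)
    for _ in range(_MAX_REJECTION_TRIES):
        mi = int(rng.integers(n))
        fi = int(rng.integers(n - 1)) if n > 1 else mi
        if n > 1 and fi >= mi:
            fi += 1
        g_m = simulate_meiosis(parents[mi], genome, rng)
        g_f = simulate_meiosis(parents[fi], genome, rng)
        w = 1.0
        for g in (g_m, g_f):
            w *= _gamete_fitness(g, gamete_loci) if gamete_loci else 1.0
        child: Individual = {c.name: (g_m[c.name], g_f[c.name]) for c in genome.chromosomes}
        if zygote_loci:
            w *= _zygote_fitness(child, zygote_loci)
        if w >= 1.0 or rng.random() < w:
            return child
    raise ConfigurationError("selection rejected every draw; fitness configuration too severe")


def _draw_gamete(
    parent: Individual,
    genome: GenomeSpec,
    rng: np.random.Generator,
    gamete_loci: list[SelectedLocus],
) -> dict[str, Haplotype]:
    for _ in range(_MAX_REJECTION_TRIES):
        g = simulate_meiosis(parent, genome, rng)
        if not gamete_loci:
            return g
        w = _gamete_fitness(g, gamete_loci)
        if w >= 1.0 or rng.random() < w:
            return g
    raise ConfigurationError("gamete selection rejected every draw")


def simulate_population(
    genome: GenomeSpec,
    scheme: BreedingScheme,
    selection: list[SelectedLocus] | None = None,
    qtls: list[QtlEffect] | None = None,
    residual_sd: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> TruePopulation:
    """Run the breeding scheme P1 x P2 -> F1 -> F2 -> (j-2 intermating
    generations) -> DH/SELF finish and return the ground-truth population.

    ``scheme.n_census`` individuals are carried through intermating; the final
    step extracts ``scheme.n_lines`` lines.  Phenotypes are simulated for the
    traits named in ``qtls`` with i.i.d. Normal(0, residual_sd^2) residuals.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    selection = list(selection or [])
    if residual_sd <= 0:
        raise ConfigurationError("residual_sd must be > 0")
    gam_loci = [s for s in selection if s.stage == "gamete"]
    zyg_loci = [s for s in selection if s.stage == "zygote"]

    f1: Individual = {
        c.name: (_pure_hap(c.length_bp, 0), _pure_hap(c.length_bp, 1)) for c in genome.chromosomes
    }
    # F2: generation 2 of j.  Intermating: generations 3..j.
    population = [f1]
    census = scheme.census
    for _generation in range(2, scheme.j + 1):
        population = [
            _draw_offspring(population, genome, rng, gam_loci, zyg_loci) for _ in range(census)
        ]

    picks = rng.choice(census, size=scheme.n_lines, replace=census < scheme.n_lines)
    lines: list[Individual] = []
    if scheme.final_step == "DH":
        for k in picks:
            g = _draw_gamete(population[int(k)], genome, rng, gam_loci)
            lines.append({name: (hap, hap) for name, hap in g.items()})
    else:
        n_self = int(min(scheme.i, _MAX_SELF_GENERATIONS))
        for k in picks:
            ind = population[int(k)]
            for _ in range(n_self):
                for _try in range(_MAX_REJECTION_TRIES):
                    g1 = _draw_gamete(ind, genome, rng, gam_loci)
                    g2 = _draw_gamete(ind, genome, rng, gam_loci)
                    child = {c.name: (g1[c.name], g2[c.name]) for c in genome.chromosomes}
                    if not zyg_loci:
                        break
                    w = _zygote_fitness(child, zyg_loci)
                    if w >= 1.0 or rng.random() < w:
                        break
                ind = child
            lines.append(ind)

    width = len(str(scheme.n_lines))
    pop = TruePopulation(
        genome=genome,
        scheme=scheme,
        line_ids=[f"L{k + 1:0{width}d}" for k in range(scheme.n_lines)],
        haplotypes=lines,
    )

    for q in qtls or []:
        codes = pop.genotype_codes(q.chrom, np.array([q.pos_bp]))[:, 0]
        x = np.where(codes == 0, 1.0, np.where(codes == 1, -1.0, 0.0))
        pop.phenotypes.setdefault(q.trait, np.zeros(pop.n_lines))
        pop.phenotypes[q.trait] = pop.phenotypes[q.trait] + q.a * x
    for trait in list(pop.phenotypes):
        pop.phenotypes[trait] = pop.phenotypes[trait] + rng.normal(0.0, residual_sd, pop.n_lines)
    return pop


def simulate_observations(
    pop: TruePopulation,
    snps: pd.DataFrame,
    coverage: float,
    error_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> ObservationMatrix:
    """Low-coverage allele observations: per line x SNP the read count is
    Poisson(``coverage``) and each read reports the true parental allele with
    probability 1 - ``error_rate`` (heterozygous sites transmit either allele
    with probability 1/2 before error)."""
    if coverage < 0:
        raise ConfigurationError("coverage must be >= 0")
    if not (0.0 <= error_rate < 0.5):
        raise ConfigurationError("error_rate must be in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    snps = validate_snp_table(snps)
    n_lines, n_snps = pop.n_lines, len(snps)
    n_p1 = np.zeros((n_lines, n_snps), dtype=np.int32)
    n_p2 = np.zeros((n_lines, n_snps), dtype=np.int32)
    for chrom, sub in snps.groupby("chrom", sort=False):
        cols = sub.index.to_numpy()
        codes = pop.genotype_codes(str(chrom), sub["pos"].to_numpy())
        n = rng.poisson(coverage, size=codes.shape)
        p1 = np.where(codes == 0, 1.0 - error_rate, np.where(codes == 1, error_rate, 0.5))
        k1 = rng.binomial(n, p1)
        n_p1[:, cols] = k1
        n_p2[:, cols] = n - k1
    return ObservationMatrix(list(pop.line_ids), snps, n_p1, n_p2)
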