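"""Genome and breeding-scheme specifications.

A genome is a set of chromosomes, each with a physical length (bp) and an
F2-scale genetic length (cM, the map length measured over a single meiosis).
The bp <-> cM relationship is a monotone piecewise-linear map; by default it
is linear (uniform recombination rate along the chromosome), but knots can be
supplied to model e.g. centromeric recombination suppression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Chromosome",
    "GenomeSpec",
    "BreedingScheme",
    "QtlEffect",
    "SelectedLocus",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when a genome or scheme specification is internally inconsistent."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ConfigurationError(f"chromosome {self.name}: length_bp must be >= 1")
        if self.length_cm <= 0:
            raise ConfigurationError(f"chromosome {self.name}: length_cm must be > 0")


@dataclass
class GenomeSpec:
    """Physical frame plus F2-scale genetic map.

    Parameters
    ----------
    chromosomes
        Ordered chromosome descriptions.
    snp_positions
        Per-chromosome sorted physical SNP positions (1-based bp).
    cm_knots
        Optional per-chromosome ``(bp_array, cm_array)`` monotone anchors for
        the bp->cM map. When absent the map is linear from (1, 0) to
        (length_bp, length_cm).
    """

    chromosomes: list[Chromosome]
    snp_positions: dict[str, np.ndarray] = field(default_factory=dict)
    cm_knots: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names")
        self._by_name = {c.name: c for c in self.chromosomes}
        for name, pos in list(self.snp_positions.items()):
            pos = np.asarray(pos, dtype=np.int64)
            if name not in self._by_name:
                raise ConfigurationError(f"SNP positions for unknown chromosome {name}")
            if pos.size and (pos[0] < 1 or pos[-1] > self._by_name[name].length_bp):
                raise ConfigurationError(f"SNP position outside chromosome {name}")
            if np.any(np.diff(pos) < 0):
                raise ConfigurationError(f"SNP positions not sorted on {name}")
            self.snp_positions[name] = pos
        for name, (bp, cm) in list(self.cm_knots.items()):
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            chrom = self._by_name.get(name)
            if chrom is None:
                raise ConfigurationError(f"cM knots for unknown chromosome {name}")
            if bp.shape != cm.shape or bp.size < 2:
                raise ConfigurationError(f"cM knots malformed on {name}")
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) < 0):
                raise ConfigurationError(f"cM knots not monotone on {name}")
            if not math.isclose(cm[-1], chrom.length_cm, rel_tol=1e-9):
                raise ConfigurationError(
                    f"{name}: genetic length {chrom.length_cm} != cm_of_bp at last bp {cm[-1]}"
                )
            self.cm_knots[name] = (bp, cm)

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def uniform(
        cls,
        chromosomes: list[tuple[str, int, float]],
        snps_per_chrom: int | dict[str, int] | None = None,
    ) -> "GenomeSpec":
        """Genome with a linear bp<->cM map and evenly spaced SNPs."""
        chroms = [Chromosome(n, int(lb), float(lc)) for n, lb, lc in chromosomes]
        snp_positions: dict[str, np.ndarray] = {}
        if snps_per_chrom is not None:
            for c in chroms:
                k = snps_per_chrom[c.name] if isinstance(snps_per_chrom, dict) else snps_per_chrom
                snp_positions[c.name] = np.linspace(1, c.length_bp, int(k)).round().astype(np.int64)
        return cls(chroms, snp_positions)

    # -- coordinate maps ----------------------------------------------------------

    def chromosome(self, name: str) -> Chromosome:
        return self._by_name[name]

    def _knots(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        if name in self.cm_knots:
            return self.cm_knots[name]
        c = self._by_name[name]
        return (np.array([1.0, float(c.length_bp)]), np.array([0.0, c.length_cm]))

    def cm_of_bp(self, name: str, bp) -> np.ndarray:
        kb, kc = self._knots(name)
        return np.interp(np.asarray(bp, dtype=float), kb, kc)

    def bp_of_cm(self, name: str, cm) -> np.ndarray:
        kb, kc = self._knots(name)
        return np.interp(np.asarray(cm, dtype=float), kc, kb)


@dataclass(frozen=True)
class BreedingScheme:
    """Intermated biparental scheme.

    ``j`` counts generations *including the two that create the F2* (so j=2 is
    a plain F2 and j=12 is ten rounds of random intermating after the F2).
    ``i`` is the number of inbreeding (selfing) generations after intermating;
    ``math.inf`` means inbred to fixation.  A doubled-haploid (DH) finish
    corresponds to i=1 in the map-expansion formula.
    """

    j: int
    i: float = 1
    n_lines: int = 200
    final_step: str = "DH"
    n_census: int | None = None  # intermating census; defaults to n_lines

    def __post_init__(self) -> None:
        if self.j < 2:
            raise ConfigurationError("j must be >= 2 (the F2 takes two generations)")
        if not (self.i >= 0):
            raise ConfigurationError("i must be >= 0 (inf allowed)")
        if self.n_lines < 2:
            raise ConfigurationError("n_lines must be >= 2")
        if self.final_step not in ("DH", "SELF"):
            raise ConfigurationError("final_step must be 'DH' or 'SELF'")
        if self.n_census is not None and self.n_census < 2:
            raise ConfigurationError("n_census must be >= 2")

    @property
    def census(self) -> int:
        return self.n_census if self.n_census is not None else self.n_lines


@dataclass(frozen=True)
class QtlEffect:
    """Additive QTL: effect ``a`` is in trait units per allele substitution,
    with genotype coded +1 for the parent-1 allele and -1 for parent-2."""

    chrom: str
    pos_bp: int
    a: float
    trait: str = "trait"


@dataclass(frozen=True)
class SelectedLocus:
    """Viability selection at one locus.

    ``fitness_p1`` / ``fitness_p2`` are relative survival probabilities of
    carriers of the parent-1 / parent-2 allele, applied by rejection sampling
    at the ``stage`` ('gamete' or 'zygote'); at least one must equal 1.
    """

    chrom: str
    pos_bp: int
    fitness_p1: float = 1.0
    fitness_p2: float = 1.0
    stage: str = "gamete"

    def __post_init__(self) -> None:
        for f in (self.fitness_p1, self.fitness_p2):
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError("fitness must be in [0, 1]")
        if max(self.fitness_p1, self.fitness_p2) != 1.0:
            raise ConfigurationError("at least one fitness must equal 1")
        if self.stage not in ("gamete", "zygote"):
            raise ConfigurationError("stage must be 'gamete' or 'zygote'")
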