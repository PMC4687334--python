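"""Genetic map expansion for intermated populations.

A population carrying the recombination of several successive meioses shows
a linkage map longer than the single-meiosis (F2-scale) map.  For a scheme
with ``j`` total generations (including the two that create the F2) and
``i`` inbreeding generations after intermating, the expected expansion
factor is

    alpha = j/2 + (2**i - 1) / 2**i

The first term counts the intermating meioses (each generation adds half a
recombination opportunity relative to the F2); the second is the fraction of
residual heterozygosity removed by ``i`` selfing generations and approaches
1 as i -> inf.  A doubled-haploid finish corresponds to i = 1.  This form
(and not variants with 2**j in the numerator, which occasionally appear in
print) is the one that yields alpha = 6.5 for (j=12, i=1) and alpha = 4 for
(j=6, i=inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .genome import BreedingScheme, ConfigurationError
from .linkmap import LinkageMap

__all__ = ["expected_expansion", "adjust_map", "observed_expansion", "ExpansionResult"]


def expected_expansion(scheme: BreedingScheme | None = None, j: int | None = None,
                       i: float | None = None) -> float:
    """Expected map-expansion factor alpha(j, i).

    Accepts either a :class:`BreedingScheme` or explicit ``j``/``i``
    (``i = math.inf`` evaluates the inbreeding term as 1).
    """
    if scheme is not None:
        j, i = scheme.j, scheme.i
    if j is None or i is None:
        raise ConfigurationError("provide a scheme or both j and i")
    if j < 2:
        raise ConfigurationError("j must be >= 2")
    if not i >= 0:
        raise ConfigurationError("i must be >= 0")
    inbred_term = 1.0 if math.isinf(i) else (2.0**i - 1.0) / 2.0**i
    return j / 2.0 + inbred_term


def adjust_map(map_: LinkageMap, alpha: float) -> LinkageMap:
    """Divide every genetic interval by ``alpha`` (F2-scale adjustment).

    Marker order and relative interval proportions are preserved exactly;
    the adjusted total length is observed/alpha.
    """
    if alpha <= 0:
        raise ConfigurationError("alpha must be > 0")
    return map_.scaled(alpha)


def observed_expansion(observed_length_cm: float, adjusted_length_cm: float) -> float:
    """Observed expansion factor, rounded half-up to 2 decimals."""
    if adjusted_length_cm <= 0:
        raise ConfigurationError("adjusted_length_cm must be > 0")
    q = Decimal(observed_length_cm) / Decimal(adjusted_length_cm)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ExpansionResult:
    alpha_expected: float
    observed_length_cm: float
    adjusted_length_cm: float

    @property
    def alpha_observed(self) -> float:
        return observed_expansion(self.observed_length_cm, self.adjusted_length_cm)


def analyze(map_: LinkageMap, scheme: BreedingScheme) -> tuple[LinkageMap, ExpansionResult]:
    """Adjust a map by its scheme's expected expansion factor."""
    alpha = expected_expansion(scheme)
    adjusted = adjust_map(map_, alpha)
    return adjusted, ExpansionResult(alpha, map_.total_cm, adjusted.total_cm)
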