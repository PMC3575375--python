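"""Infinite-alleles model: frequency spectra and the Ewens sampling formula.

Under the infinite-alleles model (IAM) every mutation creates a brand-new
allele, and the data reduce to the multiset of allele counts (the
*frequency spectrum*).  Unlike most coalescent likelihoods, the IAM
sampling probability has a closed form, the Ewens sampling formula:

    P(a_1, ..., a_n) = n! / (theta (theta+1) ... (theta+n-1))
                       * prod_j (theta / j)^{a_j} / a_j!

where ``a_j`` is the number of alleles observed in exactly ``j`` copies.
Infinite-sites data collapse to IAM form by forgetting the sites.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .errors import DomainError
from .formats import IncidenceMatrix

__all__ = ["FrequencySpectrum", "esf_probability", "spectrum_of"]


@dataclass(frozen=True)
class FrequencySpectrum:
    """Allele-count configuration: a sorted multiset of positive counts."""

    allele_counts: tuple[int, ...]

    def __post_init__(self):
        if not self.allele_counts:
            raise DomainError("spectrum needs at least one allele")
        if any(c < 1 for c in self.allele_counts):
            raise DomainError("allele counts must be positive")
        object.__setattr__(
            self, "allele_counts", tuple(sorted(self.allele_counts, reverse=True))
        )

    @property
    def n(self) -> int:
        """Sample size: sum of allele counts."""
        return sum(self.allele_counts)

    @property
    def counts_of_counts(self) -> dict[int, int]:
        """a_j = number of alleles observed in exactly j copies."""
        return dict(Counter(self.allele_counts))


def esf_probability(s: FrequencySpectrum, theta: float) -> float:
    """Ewens sampling formula: exact probability of a frequency spectrum."""
    if theta <= 0:
        raise DomainError(f"theta must be > 0, got {theta}")
    n = s.n
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    p = math.factorial(n) / rising
    for j, a_j in s.counts_of_counts.items():
        p *= (theta / j) ** a_j / math.factorial(a_j)
    return p


def spectrum_of(m: IncidenceMatrix) -> FrequencySpectrum:
    """Collapse infinite-sites data to its IAM frequency spectrum."""
    return FrequencySpectrum(tuple(freq for _, freq in m.rows))
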