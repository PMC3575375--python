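"""Forward coalescent simulator under the infinite-sites model.

The simulator is the package's independent Monte-Carlo oracle for the
exact recursion, and its fixture generator.  Time runs in coalescent
units: with ``k`` active lineages the waiting time to the next
coalescence is exponential with rate ``k (k - 1) / 2``, and mutations
fall on each lineage as a Poisson process of rate ``theta / 2`` per unit
time, every mutation creating a brand-new segregating site.  Under this
scale the pairwise-difference law for n = 2 is
``P(S = j) = theta^j / (1 + theta)^(j+1)``.

Randomness comes from NumPy's PCG64 generator (``numpy.random.default_rng``),
seeded explicitly; the same seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .formats import IncidenceMatrix
from .genetree import GeneTree, Node

__all__ = [
    "SimConfig",
    "simulate_ism_sample",
    "mc_probability_estimate",
    "pairwise_difference_counts",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings: sample size, mutation rate, seed, replicates."""

    n: int
    theta: float
    seed: int
    reps: int = 1

    def __post_init__(self):
        if self.n < 1:
            raise DomainError(f"sample size must be >= 1, got {self.n}")
        if self.theta <= 0:
            raise DomainError(f"theta must be > 0, got {self.theta}")
        if self.reps < 1:
            raise DomainError(f"reps must be >= 1, got {self.reps}")


def _simulate_mutation_sets(
    n: int, theta: float, rng: np.random.Generator
) -> list[frozenset[int]]:
    """One coalescent run; returns per-sample sets of mutation (site) ids."""
    if n == 1:
        return [frozenset()]
    # lineage -> set of sampled leaves beneath it
    lineages: list[set[int]] = [{i} for i in range(n)]
    sites: list[set[int]] = []  # site id -> carrier leaves
    k = n
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        # mutations on each lineage over this epoch
        hits = rng.poisson(theta / 2.0 * t, size=k)
        for lin, h in zip(lineages, hits):
            for _ in range(h):
                sites.append(set(lin))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        lineages[i] |= lineages[j]
        lineages.pop(j)
        k -= 1
    haplotypes = [set() for _ in range(n)]
    for sid, carriers in enumerate(sites):
        for leaf in carriers:
            haplotypes[leaf].add(sid)
    return [frozenset(h) for h in haplotypes]


def simulate_ism_sample(c: SimConfig) -> IncidenceMatrix:
    """Simulate one infinite-sites dataset as an incidence matrix.

    Haplotypes are collapsed to distinct patterns with counts (first
    appearance order); sites are labelled S1, S2, ... in order of
    occurrence in time.  All emitted sites are segregating by
    construction.  Deterministic given the seed.
    """
    rng = np.random.default_rng(c.seed)
    haplotypes = _simulate_mutation_sets(c.n, c.theta, rng)
    return _matrix_from_haplotypes(haplotypes)


def _matrix_from_haplotypes(haplotypes: list[frozenset[int]]) -> IncidenceMatrix:
    site_ids = sorted(set().union(*haplotypes)) if haplotypes else []
    labels = tuple(f"S{i + 1}" for i in range(len(site_ids)))
    counts: dict[frozenset[int], int] = {}
    order: list[frozenset[int]] = []
    for h in haplotypes:
        if h in counts:
            counts[h] += 1
        else:
            counts[h] = 1
            order.append(h)
    rows = tuple(
        (tuple(1 if sid in h else 0 for sid in site_ids), counts[h]) for h in order
    )
    return IncidenceMatrix(labels, rows)


def _shape_key_from_haplotypes(haplotypes: list[frozenset[int]]) -> str:
    """Unlabelled canonical key of the gene tree, built directly.

    Fast path used by the Monte-Carlo oracle: skips matrix validation
    and phylogeny checking (the simulator cannot produce homoplasy).
    """
    counts: dict[frozenset[int], int] = {}
    for h in haplotypes:
        counts[h] = counts.get(h, 0) + 1
    carriers: dict[int, int] = {}
    for h in haplotypes:
        for sid in h:
            carriers[sid] = carriers.get(sid, 0) + 1
    root = Node(None, 0)
    for pat, freq in counts.items():
        path = sorted(pat, key=lambda s: (-carriers[s], s))
        node = root
        for sid in path:
            for child in node.children:
                if child.site == sid:
                    node = child
                    break
            else:
                new = Node(sid, 0)
                node.children.append(new)
                node = new
        node.multiplicity += freq
    return GeneTree(root, validate=False).canonical_key(labelled=False)


def mc_probability_estimate(
    t0: GeneTree, c: SimConfig
) -> tuple[float, float]:
    """Monte-Carlo estimate of the sampling probability of a gene tree.

    Simulates ``c.reps`` datasets of size ``t0.n`` and reports the
    fraction whose gene tree is shape-and-multiplicity isomorphic to
    ``t0`` (site labels of simulated data are arbitrary, so matching is
    on the unlabelled canonical key), with the binomial standard error.

    For configurations with a shape automorphism this unlabelled
    frequency differs from the labelled recursion probability by the
    automorphism order; see the methods note.
    """
    target = t0.canonical_key(labelled=False)
    n = t0.n
    rng = np.random.default_rng(c.seed)
    hits = 0
    for _ in range(c.reps):
        haplotypes = _simulate_mutation_sets(n, c.theta, rng)
        if _shape_key_from_haplotypes(haplotypes) == target:
            hits += 1
    p = hits / c.reps
    se = float(np.sqrt(p * (1.0 - p) / c.reps))
    return p, se


def pairwise_difference_counts(c: SimConfig) -> np.ndarray:
    """Number of segregating sites in each of ``c.reps`` samples of size 2.

    Distributed as ``P(S = j) = theta^j / (1 + theta)^(j+1)``
    (geometric); used for goodness-of-fit checks of the simulator.
    Vectorized: for n = 2 the tree height T is Exp(1) and
    S | T ~ Poisson(theta * T).
    """
    if c.n != 2:
        raise DomainError("pairwise differences are defined for n = 2")
    rng = np.random.default_rng(c.seed)
    t = rng.exponential(1.0, size=c.reps)
    return rng.poisson(c.theta * t)
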