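"""The ancestral-configuration DAG and the exact likelihood recursion.

Every infinite-sites configuration ``T`` (a gene tree with allele
multiplicities) satisfies the backward recursion

    n (n - 1 + theta) P(T) =   sum_{k in S0} n (n_k - 1) P(C_k T)
                             + theta * sum_{k in S1}           P(M_k T)
                             + theta * sum_{k in S2} (n_i + 1) P(M_k T)

where S0 are the alleles that can coalesce (n_k >= 2), S1 the singleton
alleles whose terminal mutation removal creates a new type (first kind),
S2 those whose removal merges into an existing allele i with n_i copies
(second kind), and P(MRCA) = 1 is the initial condition.

This module discovers the full DAG of ancestral configurations by
breadth-first traversal (deduplicated by labelled canonical key), then
solves the recursion bottom-up by level.  On the same graph it counts
and enumerates configurations and genealogies (event paths from the data
to the MRCA), and profiles the number of configurations per level —
`P(T)` is a sum over exactly these paths, so their number measures the
cost of the exact computation.

Pluggable *output processors* receive a callback for every discovered
configuration and every edge, in deterministic order, so consumers can
stream results (counts, plots, traces) while the traversal runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Sequence

from .errors import CapExceededError, DomainError
from .genetree import Event, GeneTree, apply_event, enumerate_events

__all__ = [
    "RecursionGraph",
    "LevelProfile",
    "GenealogyPath",
    "RecursionProcessor",
    "build_recursion_graph",
    "exact_probability",
    "count_configurations",
    "count_genealogies",
    "enumerate_configurations",
    "enumerate_genealogies",
    "profile_levels",
]

DEFAULT_CAP = 10_000_000


class RecursionProcessor:
    """Base class for output processors attached to the graph traversal.

    ``on_configuration`` fires exactly once per distinct configuration
    discovered (in descending level, key-lexicographic order);
    ``on_edge`` fires exactly once per event edge.
    """

    def on_configuration(self, key: str, tree: GeneTree, level: int) -> None:  # noqa: D102
        pass

    def on_edge(self, parent_key: str, event: Event, child_key: str) -> None:  # noqa: D102
        pass


@dataclass
class RecursionGraph:
    """Level-stratified DAG of ancestral configurations.

    Acyclic by construction: every edge drops the level (n + m) by one.
    ``configurations`` maps labelled canonical keys to gene trees;
    ``edges`` maps each key to its ordered events with successor keys;
    ``levels`` maps each level to its keys in lexicographic order.
    """

    configurations: dict[str, GeneTree]
    edges: dict[str, list[tuple[Event, str]]]
    levels: dict[int, list[str]]
    root_key: str
    mrca_key: str

    @property
    def num_configurations(self) -> int:
        return len(self.configurations)

    @property
    def num_edges(self) -> int:
        return sum(len(e) for e in self.edges.values())


@dataclass(frozen=True)
class LevelProfile:
    """Distinct-configuration counts per recursion level.

    Levels form the contiguous range 1..(n+m); the counts sum to the
    total number of ancestral configurations.
    """

    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class GenealogyPath:
    """One complete ordered event sequence from the data to the MRCA."""

    events: tuple[Event, ...]

    def __len__(self) -> int:
        return len(self.events)


def build_recursion_graph(
    t0: GeneTree,
    processors: Sequence[RecursionProcessor] = (),
    cap: int = DEFAULT_CAP,
) -> RecursionGraph:
    """Discover all ancestral configurations reachable from ``t0``.

    Breadth-first by level, de-duplicating configurations by labelled
    canonical key.  Raises :class:`CapExceededError` once more than
    ``cap`` configurations have been discovered.
    """
    t0.validate()
    root_key = t0.canonical_key(True)
    configurations: dict[str, GeneTree] = {root_key: t0}
    edges: dict[str, list[tuple[Event, str]]] = {}
    levels: dict[int, list[str]] = {}
    mrca_key: str | None = None

    frontier: dict[str, GeneTree] = {root_key: t0}
    level = t0.level
    while frontier:
        keys = sorted(frontier)
        levels[level] = keys
        next_frontier: dict[str, GeneTree] = {}
        for key in keys:
            tree = frontier[key]
            for proc in processors:
                proc.on_configuration(key, tree, level)
            if tree.is_mrca():
                mrca_key = key
                edges[key] = []
                continue
            out: list[tuple[Event, str]] = []
            for event in enumerate_events(tree):
                child = apply_event(tree, event)
                child_key = child.canonical_key(True)
                if child_key not in configurations:
                    configurations[child_key] = child
                    if len(configurations) > cap:
                        raise CapExceededError(
                            f"configuration cap of {cap} exceeded", cap
                        )
                    next_frontier[child_key] = child
                out.append((event, child_key))
                for proc in processors:
                    proc.on_edge(key, event, child_key)
            edges[key] = out
        frontier = next_frontier
        level -= 1

    assert mrca_key is not None, "traversal must terminate at the MRCA"
    return RecursionGraph(configurations, edges, levels, root_key, mrca_key)


def exact_probability(
    t0: GeneTree,
    theta,
    mode: str = "float",
    cap: int = DEFAULT_CAP,
):
    """Exact sampling probability of ``t0`` and all its ancestral states.

    Solves the likelihood recursion bottom-up by level over the
    configuration DAG, starting from P(MRCA) = 1.  Returns
    ``(P(t0), {key: P})`` with the probability of every ancestral
    configuration included.

    ``mode="float"`` computes in double precision; ``mode="exact-rational"``
    computes with :class:`fractions.Fraction` (theta must be rational:
    an int, a Fraction, or a string like ``"1/2"``).
    """
    if mode not in ("float", "exact-rational"):
        raise DomainError(f"unknown mode {mode!r}")
    if mode == "exact-rational":
        try:
            theta_val = Fraction(theta)
        except (ValueError, TypeError) as exc:
            raise DomainError(f"theta {theta!r} is not rational") from exc
    else:
        theta_val = float(theta)
    if theta_val <= 0:
        raise DomainError(f"theta must be > 0, got {theta}")

    graph = build_recursion_graph(t0, cap=cap)
    one = Fraction(1) if mode == "exact-rational" else 1.0
    probs: dict[str, object] = {graph.mrca_key: one}
    for level in sorted(graph.levels):
        for key in graph.levels[level]:
            if key == graph.mrca_key:
                continue
            tree = graph.configurations[key]
            n = tree.n
            total = sum(
                event.coefficient(theta_val) * probs[succ]
                for event, succ in graph.edges[key]
            )
            probs[key] = total / (n * (n - 1 + theta_val))
    return probs[graph.root_key], probs


def count_configurations(t0: GeneTree, cap: int = DEFAULT_CAP) -> int:
    """Number of distinct ancestral configurations, data and MRCA included."""
    return build_recursion_graph(t0, cap=cap).num_configurations


def count_genealogies(t0: GeneTree, cap: int = DEFAULT_CAP) -> int:
    """Number of distinct event paths from the data to the MRCA.

    Dynamic programming over the DAG with exact integer arithmetic:
    count(MRCA) = 1 and count(T) = sum over events of count(successor).
    """
    graph = build_recursion_graph(t0, cap=cap)
    counts: dict[str, int] = {graph.mrca_key: 1}
    for level in sorted(graph.levels):
        for key in graph.levels[level]:
            if key == graph.mrca_key:
                continue
            counts[key] = sum(counts[succ] for _, succ in graph.edges[key])
    return counts[graph.root_key]


def enumerate_configurations(
    t0: GeneTree, cap: int = DEFAULT_CAP
) -> Iterator[GeneTree]:
    """Yield every distinct ancestral configuration exactly once.

    Order: descending level, then labelled-key lexicographic.
    """
    graph = build_recursion_graph(t0, cap=cap)
    for level in sorted(graph.levels, reverse=True):
        for key in graph.levels[level]:
            yield graph.configurations[key]


def enumerate_genealogies(
    t0: GeneTree, cap: int | None = None
) -> Iterator[GenealogyPath]:
    """Depth-first enumeration of all genealogies (event paths) of ``t0``.

    Paths are emitted in event-order-lexicographic order.  When ``cap``
    is given, raises :class:`CapExceededError` after yielding that many
    paths.
    """
    t0.validate()
    emitted = 0

    def dfs(tree: GeneTree, prefix: tuple[Event, ...]) -> Iterator[GenealogyPath]:
        nonlocal emitted
        if tree.is_mrca():
            if cap is not None and emitted >= cap:
                raise CapExceededError(f"genealogy cap of {cap} exceeded", cap)
            emitted += 1
            yield GenealogyPath(prefix)
            return
        for event in enumerate_events(tree):
            yield from dfs(apply_event(tree, event), prefix + (event,))

    yield from dfs(t0, ())


class _LevelCounter(RecursionProcessor):
    def __init__(self):
        self.counts: dict[int, int] = {}

    def on_configuration(self, key, tree, level):
        self.counts[level] = self.counts.get(level, 0) + 1


def profile_levels(t0: GeneTree, cap: int = DEFAULT_CAP) -> LevelProfile:
    """Count distinct configurations at each level of the recursion graph.

    Implemented as an output processor, so the counts accrue while the
    traversal runs (a live consumer can subscribe the same way).
    """
    counter = _LevelCounter()
    build_recursion_graph(t0, processors=[counter], cap=cap)
    return LevelProfile(dict(sorted(counter.counts.items())))
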