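"""Gene trees and backward events for the infinite-sites model.

A *gene tree* is the sufficient statistic for infinite-sites (ISM) data:
a rooted tree whose non-root nodes each carry one mutation (a segregating
site), with a non-negative allele multiplicity on every node.  An allele
with multiplicity ``n_k`` sits at the node whose root path carries exactly
the mutations of that haplotype; the root holds the fully ancestral
haplotype.  The sample size ``n`` is the sum of multiplicities and ``m``
is the number of mutation nodes.

Looking backward in time, three kinds of events reduce a configuration by
one *level* (level = n + m):

* **coalescence** of two copies of allele ``k`` (requires ``n_k >= 2``),
  with rate coefficient ``n (n_k - 1)`` (``n`` the current sample size);
* **mutation removal of the first kind**: removing the terminal mutation
  of a singleton allele creates an allele type not currently present
  (the parent node has multiplicity 0); coefficient ``theta * 1``;
* **mutation removal of the second kind**: the removal merges the
  singleton into an existing allele ``i`` (the *merge allele*, the parent
  node, with multiplicity ``n_i >= 1``); coefficient ``theta * (n_i + 1)``.

The single-lineage, zero-mutation configuration is the MRCA (most recent
common ancestor), the terminal state of the backward recursion.

Event coefficients are kept symbolic in ``theta``: each event stores an
integer factor and the power of theta (0 or 1); numeric substitution
happens in :mod:`coalescent_exact.recursion`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

from .errors import InvariantError

__all__ = [
    "Node",
    "GeneTree",
    "Event",
    "EventKind",
    "enumerate_events",
    "apply_event",
    "canonical_key",
]


class EventKind(Enum):
    COALESCENCE = "coalescence"
    MUTATION_FIRST = "mutation_first"
    MUTATION_SECOND = "mutation_second"


@dataclass
class Node:
    """One gene-tree node: the root (site is None) or a mutation node."""

    site: str | None
    multiplicity: int
    children: list["Node"] = field(default_factory=list)

    def copy(self) -> "Node":
        return Node(self.site, self.multiplicity, [c.copy() for c in self.children])


class GeneTree:
    """Rooted mutation tree with allele multiplicities (an ISM configuration).

    Parameters
    ----------
    root:
        Root node; its ``site`` must be ``None``.
    validate:
        Check the structural invariants on construction (default True).
    """

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # -- basic quantities ------------------------------------------------

    @property
    def n(self) -> int:
        """Sample size: sum of allele multiplicities over all nodes."""
        return sum(node.multiplicity for node, _ in self.iter_nodes())

    @property
    def num_mutations(self) -> int:
        """Number of mutation (non-root) nodes."""
        return sum(1 for node, _ in self.iter_nodes() if node.site is not None)

    @property
    def level(self) -> int:
        """Recursion level n + m; each backward event decreases it by 1."""
        return self.n + self.num_mutations

    def is_mrca(self) -> bool:
        """True for the terminal configuration: one lineage, no mutations."""
        return self.num_mutations == 0 and self.n == 1

    # -- traversal -------------------------------------------------------

    def iter_nodes(self) -> Iterator[tuple[Node, tuple[int, ...]]]:
        """Yield (node, path) in preorder; path = child indices from root."""
        stack: list[tuple[Node, tuple[int, ...]]] = [(self.root, ())]
        while stack:
            node, path = stack.pop()
            yield node, path
            for i in range(len(node.children) - 1, -1, -1):
                stack.append((node.children[i], path + (i,)))

    def node_at(self, path: tuple[int, ...]) -> Node:
        node = self.root
        for i in path:
            node = node.children[i]
        return node

    def site_labels(self) -> list[str]:
        return [n.site for n, _ in self.iter_nodes() if n.site is not None]

    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy(), validate=False)

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`InvariantError` on any structural violation."""
        if self.root.site is not None:
            raise InvariantError("root node must not carry a site label")
        seen: set[str] = set()
        total = 0
        for node, path in self.iter_nodes():
            if node.multiplicity < 0:
                raise InvariantError(f"negative multiplicity at {node.site!r}")
            total += node.multiplicity
            if node.site is not None:
                if node.site in seen:
                    raise InvariantError(f"duplicate site label {node.site!r}")
                seen.add(node.site)
                if node.multiplicity == 0 and not node.children:
                    raise InvariantError(
                        f"leaf mutation node {node.site!r} has multiplicity 0"
                    )
        if total < 1:
            raise InvariantError("sample size n must be >= 1")

    # -- identity --------------------------------------------------------

    def canonical_key(self, labelled: bool = True) -> str:
        """Canonical text encoding, invariant under child reordering.

        With ``labelled=True`` site identity is preserved; equal keys mean
        equal configurations of the same sites.  With ``labelled=False``
        labels are erased and equal keys mean shape-and-multiplicity
        isomorphism (used when matching against simulated data whose site
        labels are arbitrary).
        """
        return _node_key(self.root, labelled)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneTree):
            return NotImplemented
        return self.canonical_key(True) == other.canonical_key(True)

    def __hash__(self) -> int:
        return hash(self.canonical_key(True))

    def __repr__(self) -> str:
        return f"GeneTree({self.canonical_key(True)})"


def _node_key(node: Node, labelled: bool) -> str:
    label = "" if node.site is None else (node.site if labelled else "*")
    child_keys = sorted(_node_key(c, labelled) for c in node.children)
    return f"({label}|{node.multiplicity}{''.join(child_keys)})"


def canonical_key(t: GeneTree, labelled: bool = True) -> str:
    """Functional alias for :meth:`GeneTree.canonical_key`."""
    return t.canonical_key(labelled)


@dataclass(frozen=True)
class Event:
    """One backward step with its exact rate coefficient.

    The coefficient is ``factor * theta**theta_power``:
    ``n (n_k - 1)`` for a coalescence (theta_power 0), ``theta`` for a
    removal of the first kind, ``theta * (n_i + 1)`` for the second kind
    where ``n_i`` is the merge allele's multiplicity before the removal.
    Nodes are referenced by their child-index path from the root, valid
    for the tree the event was enumerated on (and its copies).
    """

    kind: EventKind
    target: tuple[int, ...]
    merge_target: tuple[int, ...] | None
    factor: int
    theta_power: int

    def coefficient(self, theta):
        """Numeric coefficient at a given theta (float or Fraction)."""
        return self.factor * theta**self.theta_power if self.theta_power else self.factor

    def describe(self, t: GeneTree) -> str:
        node = t.node_at(self.target)
        what = node.site if node.site is not None else "root"
        return f"{self.kind.value}({what})"


def _root_path_labels(t: GeneTree, path: tuple[int, ...]) -> tuple[str, ...]:
    labels = []
    node = t.root
    for i in path:
        node = node.children[i]
        labels.append(node.site or "")
    return tuple(labels)


def enumerate_events(t: GeneTree) -> list[Event]:
    """All applicable backward events of a configuration.

    Returns exactly the events of the three-part partition driving the
    likelihood recursion: one coalescence per allele with multiplicity
    >= 2, and one removal per leaf mutation node with multiplicity 1,
    classified first/second kind by whether the parent type is absent
    (multiplicity 0) or present.  Order is deterministic: coalescences,
    then first kind, then second kind, each sorted by the target node's
    root-path labels.  The MRCA yields an empty list.
    """
    t.validate()
    n = t.n
    coal: list[tuple[tuple[str, ...], Event]] = []
    first: list[tuple[tuple[str, ...], Event]] = []
    second: list[tuple[tuple[str, ...], Event]] = []
    for node, path in t.iter_nodes():
        if node.multiplicity >= 2:
            coal.append(
                (
                    _root_path_labels(t, path),
                    Event(
                        EventKind.COALESCENCE,
                        path,
                        None,
                        n * (node.multiplicity - 1),
                        0,
                    ),
                )
            )
        if node.site is not None and not node.children and node.multiplicity == 1:
            parent = t.node_at(path[:-1])
            sort_key = _root_path_labels(t, path)
            if parent.multiplicity == 0:
                first.append(
                    (sort_key, Event(EventKind.MUTATION_FIRST, path, None, 1, 1))
                )
            else:
                second.append(
                    (
                        sort_key,
                        Event(
                            EventKind.MUTATION_SECOND,
                            path,
                            path[:-1],
                            parent.multiplicity + 1,
                            1,
                        ),
                    )
                )
    out: list[Event] = []
    for group in (coal, first, second):
        group.sort(key=lambda kv: kv[0])
        out.extend(e for _, e in group)
    return out


def apply_event(t: GeneTree, e: Event) -> GeneTree:
    """Successor configuration after one backward event.

    The input tree is not modified; the result has level ``t.level - 1``.
    Raises :class:`InvariantError` if the event is not applicable.
    """
    new = t.copy()
    target = new.node_at(e.target)
    if e.kind is EventKind.COALESCENCE:
        if target.multiplicity < 2:
            raise InvariantError("coalescence requires multiplicity >= 2")
        target.multiplicity -= 1
    else:
        if target.site is None or target.children or target.multiplicity != 1:
            raise InvariantError(
                "mutation removal requires a leaf mutation node with multiplicity 1"
            )
        parent = new.node_at(e.target[:-1])
        if e.kind is EventKind.MUTATION_FIRST and parent.multiplicity != 0:
            raise InvariantError("first-kind removal requires an absent parent type")
        if e.kind is EventKind.MUTATION_SECOND and parent.multiplicity < 1:
            raise InvariantError("second-kind removal requires a present merge allele")
        parent.children.pop(e.target[-1])
        parent.multiplicity += 1
    new.validate()
    return new


# -- convenience constructors used across tests and the simulator --------


def single_allele_tree(n: int) -> GeneTree:
    """A sample of n copies of one allele, no mutations."""
    return GeneTree(Node(None, n))


def chain_tree(n_root: int, sites: list[str], n_tip: int) -> GeneTree:
    """Root (mult n_root) above a chain of mutations ending at mult n_tip."""
    node = Node(sites[-1], n_tip) if sites else None
    for s in reversed(sites[:-1]):
        node = Node(s, 0, [node])
    root = Node(None, n_root, [node] if node is not None else [])
    return GeneTree(root)
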