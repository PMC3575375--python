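"""Perfect-phylogeny tests and gene-tree construction for binary data.

Under the infinite-sites model every mutation hits a fresh site, so the
carrier sets of any two sites must be disjoint or nested: the data admit
a *perfect phylogeny*.  Two classic tests are provided:

* the four-gamete test: a site pair is incompatible when its rows
  exhibit the gametes 01, 10 and 11 (rooted/polarized variant; the
  unrooted classic additionally requires 00);
* Gusfield's algorithm: sort columns as binary numbers and check that
  all carriers of a column agree on the nearest 1-column to the left —
  linear in the number of matrix cells.

When the data pass, :func:`build_gene_tree` constructs the unique rooted
mutation tree, placing each haplotype's frequency on the node whose
root-path mutation set equals the haplotype's 1-set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PhylogenyError
from .formats import IncidenceMatrix
from .genetree import GeneTree, Node

__all__ = [
    "PhylogenyReport",
    "four_gamete_check",
    "gusfield_check",
    "build_gene_tree",
]


@dataclass(frozen=True)
class PhylogenyReport:
    """Verdict of a perfect-phylogeny test.

    ``witness`` names the first (in column order) violating pair of site
    labels when the data are incompatible; it is absent otherwise.
    """

    compatible: bool
    witness: tuple[str, str] | None
    algorithm: str


def _pattern_array(m: IncidenceMatrix) -> np.ndarray:
    return np.array([p for p, _ in m.rows], dtype=np.int8).reshape(len(m.rows), m.num_sites)


def _find_witness(a: np.ndarray, labels, rooted: bool) -> tuple[str, str] | None:
    """First violating site pair in column order, or None.

    Frequencies are irrelevant: only which row patterns exist matters.
    """
    ncols = a.shape[1]
    for j in range(ncols):
        cj = a[:, j].astype(bool)
        for k in range(j + 1, ncols):
            ck = a[:, k].astype(bool)
            g01 = bool(np.any(~cj & ck))
            g10 = bool(np.any(cj & ~ck))
            g11 = bool(np.any(cj & ck))
            if rooted:
                bad = g01 and g10 and g11
            else:
                bad = g01 and g10 and g11 and bool(np.any(~cj & ~ck))
            if bad:
                return (labels[j], labels[k])
    return None


def four_gamete_check(m: IncidenceMatrix, rooted: bool = True) -> PhylogenyReport:
    """Pairwise site-compatibility test.

    ``rooted=True`` (the default, matching polarized 0/1 data): a pair is
    incompatible when gametes 01, 10 and 11 all occur, i.e. the carrier
    sets are neither disjoint nor nested.  ``rooted=False``: the classic
    unrooted test, requiring all four gametes including 00.
    """
    if m.num_sites < 2:
        return PhylogenyReport(True, None, "four-gamete")
    witness = _find_witness(_pattern_array(m), m.site_labels, rooted)
    return PhylogenyReport(witness is None, witness, "four-gamete")


def gusfield_check(m: IncidenceMatrix) -> PhylogenyReport:
    """Gusfield's linear-time perfect-phylogeny test (rooted verdict).

    Columns are radix-sorted as binary numbers (most significant bit =
    first row) in decreasing order; the matrix has a perfect phylogeny
    iff, for every column, all rows carrying it agree on the index of
    the nearest 1-column to its left (the L-value).  On failure the
    witness pair is recovered by a direct pairwise scan so the reported
    labels demonstrably violate the criterion.
    """
    if m.num_sites < 2:
        return PhylogenyReport(True, None, "gusfield")
    a = _pattern_array(m)
    nrows, ncols = a.shape
    # sort columns as binary numbers, descending; stable so duplicate
    # columns keep input order
    weights = 1 << np.arange(nrows - 1, -1, -1, dtype=object)
    values = [int(sum(int(a[i, j]) * int(weights[i]) for i in range(nrows))) for j in range(ncols)]
    order = sorted(range(ncols), key=lambda j: -values[j])
    s = a[:, order]
    # L[i, j] = 1-based index of rightmost column k < j with s[i, k] = 1
    compatible = True
    for j in range(ncols):
        lvals = set()
        for i in range(nrows):
            if s[i, j]:
                left = 0
                for k in range(j - 1, -1, -1):
                    if s[i, k]:
                        left = k + 1
                        break
                lvals.add(left)
                if len(lvals) > 1:
                    break
        if len(lvals) > 1:
            compatible = False
            break
    witness = None
    if not compatible:
        witness = _find_witness(a, m.site_labels, rooted=True)
    return PhylogenyReport(compatible, witness, "gusfield")


def build_gene_tree(m: IncidenceMatrix) -> GeneTree:
    """Build the gene tree of a (rooted-)compatible incidence matrix.

    Each site becomes one mutation node; duplicate columns form a chain
    in input column order.  Each haplotype's frequency is the
    multiplicity of the node whose root-path 1-set equals the
    haplotype's 1-set; the root carries the frequency of the all-zero
    haplotype (0 if absent).  Raises :class:`PhylogenyError` with the
    witness pair when the matrix is incompatible.
    """
    report = gusfield_check(m)
    if not report.compatible:
        raise PhylogenyError(
            f"data do not admit a perfect phylogeny; witness sites {report.witness}",
            witness=report.witness,
        )
    patterns = [frozenset(j for j, c in enumerate(p) if c) for p, _ in m.rows]
    freqs = [f for _, f in m.rows]
    carriers = [
        sum(f for p, f in zip(patterns, freqs) if j in p) for j in range(m.num_sites)
    ]
    # within a haplotype, sites are totally ordered by carrier-set
    # containment; bigger carrier sets are closer to the root, ties
    # (duplicate columns) broken by input column order
    root = _build_tree(patterns, freqs, carriers)
    _relabel(root, m.site_labels)
    return GeneTree(root)


def _relabel(node: Node, labels) -> None:
    if node.site is not None:
        node.site = labels[node.site]
    for child in node.children:
        _relabel(child, labels)


def _build_tree(patterns, freqs, carriers) -> Node:
    """Trie insertion of haplotypes along root-to-tip mutation paths.

    ``patterns`` are frozensets of site indices; node.site holds the
    site *index* (relabelled by the caller).
    """
    root = Node(None, 0)
    for pat, freq in zip(patterns, freqs):
        path = sorted(pat, key=lambda j: (-carriers[j], j))
        node = root
        for j in path:
            for child in node.children:
                if child.site == j:
                    node = child
                    break
            else:
                new = Node(j, 0)
                node.children.append(new)
                node = new
        node.multiplicity += freq
    return root
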