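"""Reading and writing incidence matrices; Newick and DOT export.

The on-disk form of infinite-sites data is a TSV incidence matrix:
columns are segregating sites, cells are 0 (ancestral) / 1 (derived,
mutation present).  Two dialects exist:

* **haplotype-frequency**: a header of site labels ending in a column
  literally named ``freq``; one row per distinct haplotype with its
  sample count.
* **per-individual**: the same header without ``freq``; one row per
  sampled individual, repeats allowed; rows are collapsed on read.

Lines starting with ``#`` are comments.  Constant all-zero columns carry
no mutation and are dropped on read with a logged warning; all-ones
columns are legal (a mutation on the stem above the whole sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO

from .errors import FormatError
from .genetree import GeneTree, Node

__all__ = [
    "IncidenceMatrix",
    "read_incidence_matrix",
    "write_incidence_matrix",
    "to_newick",
    "to_dot",
]

logger = logging.getLogger(__name__)

FREQ_COLUMN = "freq"


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary haplotype-by-site data with per-row sample counts.

    ``site_labels`` are the ordered, unique column names; ``rows`` pairs
    each distinct 0/1 pattern with its positive frequency; ``n`` is the
    total sample size.
    """

    site_labels: tuple[str, ...]
    rows: tuple[tuple[tuple[int, ...], int], ...]

    def __post_init__(self):
        labels = self.site_labels
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate site label")
        if any(not lab for lab in labels):
            raise FormatError("empty site label")
        if not self.rows:
            raise FormatError("matrix must have at least one row")
        seen = set()
        for pattern, freq in self.rows:
            if len(pattern) != len(labels):
                raise FormatError("row length does not match number of sites")
            if any(c not in (0, 1) for c in pattern):
                raise FormatError("non-binary cell")
            if not isinstance(freq, int) or freq < 1:
                raise FormatError(f"frequency must be a positive integer, got {freq!r}")
            if pattern in seen:
                raise FormatError("duplicate row pattern")
            seen.add(pattern)

    @property
    def n(self) -> int:
        """Total sample size (sum of row frequencies)."""
        return sum(freq for _, freq in self.rows)

    @property
    def num_sites(self) -> int:
        return len(self.site_labels)


def _parse_cell(token: str, row: int, label: str) -> int:
    if token == "0":
        return 0
    if token == "1":
        return 1
    raise FormatError(
        f"non-binary cell {token!r} at row {row}, column {label!r}"
    )


def read_incidence_matrix(source: IO[str], dialect: str = "auto") -> IncidenceMatrix:
    """Parse TSV incidence data.

    ``dialect`` is ``"haplotype-frequency"``, ``"per-individual"`` or
    ``"auto"`` (decide by whether the header ends in ``freq``).
    Per-individual rows are collapsed into distinct patterns with counts;
    all-zero (non-segregating) columns are dropped with a warning.
    """
    lines = [
        line.rstrip("\n")
        for line in source
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not lines:
        raise FormatError("empty input")
    header = lines[0].split("\t")
    has_freq = header[-1] == FREQ_COLUMN
    if dialect == "auto":
        dialect = "haplotype-frequency" if has_freq else "per-individual"
    elif dialect == "haplotype-frequency" and not has_freq:
        raise FormatError(f"haplotype-frequency dialect requires a final {FREQ_COLUMN!r} column")
    elif dialect == "per-individual" and has_freq:
        raise FormatError(f"per-individual dialect must not have a {FREQ_COLUMN!r} column")
    elif dialect not in ("haplotype-frequency", "per-individual"):
        raise FormatError(f"unknown dialect {dialect!r}")

    labels = tuple(header[:-1] if has_freq else header)
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate site label in header")

    patterns: list[tuple[int, ...]] = []
    freqs: list[int] = []
    index: dict[tuple[int, ...], int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        expected = len(labels) + (1 if has_freq else 0)
        if len(cells) != expected:
            raise FormatError(f"row {lineno} has {len(cells)} fields, expected {expected}")
        pattern = tuple(
            _parse_cell(tok, lineno, labels[j]) for j, tok in enumerate(cells[: len(labels)])
        )
        if has_freq:
            try:
                freq = int(cells[-1])
            except ValueError:
                raise FormatError(f"non-integer frequency {cells[-1]!r} at row {lineno}") from None
            if freq < 1:
                raise FormatError(f"frequency {freq} <= 0 at row {lineno}")
            if pattern in index:
                raise FormatError(f"duplicate haplotype pattern at row {lineno}")
            index[pattern] = len(patterns)
            patterns.append(pattern)
            freqs.append(freq)
        else:
            if pattern in index:
                freqs[index[pattern]] += 1
            else:
                index[pattern] = len(patterns)
                patterns.append(pattern)
                freqs.append(1)
    if not patterns:
        raise FormatError("no data rows")

    # drop non-segregating (all-zero) columns
    keep = [j for j in range(len(labels)) if any(p[j] for p in patterns)]
    if len(keep) < len(labels):
        dropped = [labels[j] for j in range(len(labels)) if j not in keep]
        logger.warning("dropping non-segregating all-zero column(s): %s", ", ".join(dropped))
        labels = tuple(labels[j] for j in keep)
        collapsed: dict[tuple[int, ...], int] = {}
        order: list[tuple[int, ...]] = []
        for p, f in zip(patterns, freqs):
            q = tuple(p[j] for j in keep)
            if q in collapsed:
                collapsed[q] += f
            else:
                collapsed[q] = f
                order.append(q)
        patterns = order
        freqs = [collapsed[q] for q in order]

    return IncidenceMatrix(labels, tuple(zip(patterns, freqs)))


def write_incidence_matrix(m: IncidenceMatrix, sink: IO[str]) -> None:
    """Serialize in the haplotype-frequency dialect (round-trip safe)."""
    sink.write("\t".join(list(m.site_labels) + [FREQ_COLUMN]) + "\n")
    for pattern, freq in m.rows:
        sink.write("\t".join([str(c) for c in pattern] + [str(freq)]) + "\n")


# -- tree / graph export -------------------------------------------------


def _newick_node(node: Node, labelled_key) -> str:
    name = ("root" if node.site is None else node.site) + f"_{node.multiplicity}"
    if not node.children:
        return name
    kids = sorted(node.children, key=labelled_key)
    return "(" + ",".join(_newick_node(c, labelled_key) for c in kids) + ")" + name


def to_newick(t: GeneTree) -> str:
    """Newick string for a gene tree.

    Node names are ``<site>_<multiplicity>`` (``root_<k>`` for the root);
    no branch lengths.  Children are emitted in canonical-key order, so
    the output is invariant under child reordering of the input.
    """
    from .genetree import _node_key

    return _newick_node(t.root, lambda c: _node_key(c, True)) + ";"


def to_dot(obj) -> str:
    """Graphviz DOT text for a gene tree or a recursion graph.

    For a recursion graph: one node per ancestral configuration,
    labelled by canonical key and level, one edge per event labelled by
    kind and coefficient.  For a gene tree: one node per tree node.
    """
    from .recursion import RecursionGraph

    lines = ["digraph G {"]
    if isinstance(obj, GeneTree):
        ids: dict[int, str] = {}
        for idx, (node, path) in enumerate(obj.iter_nodes()):
            ids[id(node)] = f"n{idx}"
            name = "root" if node.site is None else node.site
            lines.append(f'  n{idx} [label="{name} x{node.multiplicity}"];')
        for node, _ in obj.iter_nodes():
            for child in node.children:
                lines.append(f"  {ids[id(node)]} -> {ids[id(child)]};")
    elif isinstance(obj, RecursionGraph):
        ids = {}
        ordered = [
            key
            for level in sorted(obj.levels, reverse=True)
            for key in obj.levels[level]
        ]
        for idx, key in enumerate(ordered):
            ids[key] = f"c{idx}"
            level = obj.configurations[key].level
            label = key.replace('"', r"\"")
            lines.append(f'  c{idx} [label="{label}\\nlevel {level}"];')
        for key in ordered:
            for event, succ in obj.edges[key]:
                coeff = (
                    f"{event.factor}"
                    if event.theta_power == 0
                    else (f"theta" if event.factor == 1 else f"{event.factor}*theta")
                )
                lines.append(
                    f'  {ids[key]} -> {ids[succ]} [label="{event.kind.value} {coeff}"];'
                )
    else:
        raise TypeError(f"cannot render {type(obj).__name__} as DOT")
    lines.append("}")
    return "\n".join(lines)
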