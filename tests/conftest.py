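"""Shared fixtures: canonical small datasets and random-matrix helpers."""

from io import StringIO

import numpy as np
import pytest
from hypothesis import settings

from coalescent_exact import (
    GeneTree,
    IncidenceMatrix,
    Node,
    read_incidence_matrix,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# the four-haplotype, four-site reference dataset: sites M1..M4, one copy
# of each haplotype (0110, 1110, 0000, 0001)
TABLE1_TSV = (
    "M1\tM2\tM3\tM4\tfreq\n"
    "0\t1\t1\t0\t1\n"
    "1\t1\t1\t0\t1\n"
    "0\t0\t0\t0\t1\n"
    "0\t0\t0\t1\t1\n"
)


@pytest.fixture
def table1_matrix() -> IncidenceMatrix:
    return read_incidence_matrix(StringIO(TABLE1_TSV))


@pytest.fixture
def table1_tree(table1_matrix) -> GeneTree:
    from coalescent_exact import build_gene_tree

    return build_gene_tree(table1_matrix)


@pytest.fixture
def mrca_tree() -> GeneTree:
    return GeneTree(Node(None, 1))


def single_allele(n: int) -> GeneTree:
    return GeneTree(Node(None, n))


def one_mutation_tree() -> GeneTree:
    """n=2: one ancestral copy, one copy carrying a single mutation."""
    return GeneTree(Node(None, 1, [Node("a", 1)]))


def two_chain_tree() -> GeneTree:
    """n=2: one ancestral copy, one copy carrying two chained mutations."""
    return GeneTree(Node(None, 1, [Node("a", 0, [Node("b", 1)])]))


def two_private_tree() -> GeneTree:
    """n=2: each copy carries its own private mutation (shape automorphism)."""
    return GeneTree(Node(None, 0, [Node("a", 1), Node("b", 1)]))


def random_matrix(rng: np.random.Generator, max_rows: int = 8, max_cols: int = 8):
    """A random binary incidence matrix (not necessarily compatible)."""
    nrows = int(rng.integers(1, max_rows + 1))
    ncols = int(rng.integers(1, max_cols + 1))
    a = rng.integers(0, 2, size=(nrows, ncols))
    # keep distinct rows and segregating columns
    rows = []
    seen = set()
    for r in a:
        t = tuple(int(x) for x in r)
        if t not in seen:
            seen.add(t)
            rows.append(t)
    keep = [j for j in range(ncols) if any(r[j] for r in rows)]
    if not keep:
        rows = [()]
        labels = ()
    else:
        labels = tuple(f"S{j + 1}" for j in range(len(keep)))
        collapsed = []
        cseen = set()
        for r in rows:
            t = tuple(r[j] for j in keep)
            if t not in cseen:
                cseen.add(t)
                collapsed.append(t)
        rows = collapsed
    freqs = [int(rng.integers(1, 4)) for _ in rows]
    return IncidenceMatrix(labels, tuple(zip(rows, freqs)))


def small_simulated_trees(num: int, seed: int, max_level: int = 8):
    """Gene trees of simulated datasets with level n + m <= max_level."""
    from coalescent_exact import SimConfig, build_gene_tree, simulate_ism_sample

    rng = np.random.default_rng(seed)
    out = []
    attempt = 0
    while len(out) < num:
        n = int(rng.integers(2, 5))
        sub = int(rng.integers(0, 2**31 - 1))
        m = simulate_ism_sample(SimConfig(n=n, theta=1.0, seed=sub))
        attempt += 1
        tree = build_gene_tree(m)
        if tree.level <= max_level:
            out.append((m, tree))
    return out
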