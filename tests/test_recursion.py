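"""Recursion graph, exact probabilities, counting and enumeration."""

from fractions import Fraction

import pytest

from coalescent_exact import (
    CapExceededError,
    DomainError,
    GeneTree,
    Node,
    RecursionProcessor,
    build_recursion_graph,
    count_configurations,
    count_genealogies,
    enumerate_configurations,
    enumerate_genealogies,
    exact_probability,
    profile_levels,
)
from conftest import (
    one_mutation_tree,
    single_allele,
    small_simulated_trees,
    two_chain_tree,
    two_private_tree,
)


def closed_form_n2(j: int, theta: float) -> float:
    """Sampling probability of n=2 data with j mutations all on one lineage.

    From the pairwise-difference law P(S=j) = theta^j / (1+theta)^(j+1);
    for j >= 2 the chain has 1/2 probability of being all on one lineage.
    """
    if j == 0:
        return 1.0 / (1.0 + theta)
    if j == 1:
        return theta / (1.0 + theta) ** 2
    if j == 2:
        return theta**2 / (2.0 * (1.0 + theta) ** 3)
    raise ValueError(j)


class TestGraph:
    def test_mrca_graph_is_trivial(self, mrca_tree):
        g = build_recursion_graph(mrca_tree)
        assert g.num_configurations == 1
        assert g.num_edges == 0
        assert g.root_key == g.mrca_key

    def test_one_mutation_graph(self):
        g = build_recursion_graph(one_mutation_tree())
        assert g.num_configurations == 3
        assert g.num_edges == 2
        assert {lvl: len(keys) for lvl, keys in g.levels.items()} == {3: 1, 2: 1, 1: 1}

    def test_every_edge_drops_one_level(self):
        for _, tree in small_simulated_trees(10, seed=3):
            g = build_recursion_graph(tree)
            for key, out in g.edges.items():
                lvl = g.configurations[key].level
                for _, succ in out:
                    assert g.configurations[succ].level == lvl - 1

    def test_processor_contract(self, table1_tree):
        class Counter(RecursionProcessor):
            def __init__(self):
                self.configs = 0
                self.edge_calls = 0

            def on_configuration(self, key, tree, level):
                self.configs += 1

            def on_edge(self, parent_key, event, child_key):
                self.edge_calls += 1

        c = Counter()
        g = build_recursion_graph(table1_tree, processors=[c])
        assert c.configs == g.num_configurations
        assert c.edge_calls == g.num_edges

    def test_cap_raises(self, table1_tree):
        with pytest.raises(CapExceededError):
            build_recursion_graph(table1_tree, cap=5)


class TestExactProbability:
    @pytest.mark.parametrize("theta", [0.1, 1.0, 10.0])
    def test_mrca_probability_is_one(self, mrca_tree, theta):
        p, all_p = exact_probability(mrca_tree, theta)
        assert p == 1.0
        assert all_p == {mrca_tree.canonical_key(True): 1.0}

    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize(
        "j, tree_fn",
        [(0, lambda: single_allele(2)), (1, one_mutation_tree), (2, two_chain_tree)],
    )
    def test_n2_closed_forms_float(self, j, tree_fn, theta):
        p, _ = exact_probability(tree_fn(), theta)
        expected = closed_form_n2(j, theta)
        assert p == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("theta", [Fraction(1, 2), Fraction(1), Fraction(2)])
    def test_n2_closed_forms_exact(self, theta):
        p0, _ = exact_probability(single_allele(2), theta, mode="exact-rational")
        p1, _ = exact_probability(one_mutation_tree(), theta, mode="exact-rational")
        p2, _ = exact_probability(two_chain_tree(), theta, mode="exact-rational")
        assert p0 == 1 / (1 + theta)
        assert p1 == theta / (1 + theta) ** 2
        assert p2 == theta**2 / (2 * (1 + theta) ** 3)

    def test_ancestral_probabilities_included_and_bounded(self, table1_tree):
        p, all_p = exact_probability(table1_tree, 1.0)
        assert len(all_p) == count_configurations(table1_tree)
        mrca_key = GeneTree(Node(None, 1)).canonical_key(True)
        for key, value in all_p.items():
            assert 0.0 < value <= 1.0
            if key != mrca_key:
                assert value < 1.0

    def test_float_and_rational_agree(self):
        for _, tree in small_simulated_trees(8, seed=57, max_level=10):
            pf, _ = exact_probability(tree, 0.5)
            pr, _ = exact_probability(tree, Fraction(1, 2), mode="exact-rational")
            assert pf == pytest.approx(float(pr), rel=1e-10)

    def test_theta_domain_errors(self, mrca_tree):
        with pytest.raises(DomainError):
            exact_probability(mrca_tree, 0.0)
        with pytest.raises(DomainError):
            exact_probability(mrca_tree, -1.0)
        with pytest.raises(DomainError):
            exact_probability(mrca_tree, "not-a-number", mode="exact-rational")

    def test_labelled_probability_on_automorphic_shape(self):
        # Two private mutations: the labelled recursion value is exactly
        # twice the unlabelled pattern probability theta^2/(2(1+theta)^3)
        # (automorphism order 2); asserted here as the documented relation.
        theta = Fraction(1)
        p, _ = exact_probability(two_private_tree(), theta, mode="exact-rational")
        assert p == theta**2 / (1 + theta) ** 3


class TestCounting:
    def test_trivial_counts(self, mrca_tree):
        assert count_configurations(mrca_tree) == 1
        assert count_genealogies(mrca_tree) == 1

    def test_one_mutation_counts(self):
        assert count_configurations(one_mutation_tree()) == 3
        assert count_genealogies(one_mutation_tree()) == 1

    def test_two_private_mutations_two_paths(self):
        t = two_private_tree()
        paths = list(enumerate_genealogies(t))
        assert count_genealogies(t) == 2
        assert len(paths) == 2
        assert all(len(p) == t.level - 1 == 3 for p in paths)

    def test_dp_count_equals_dfs_enumeration(self):
        for _, tree in small_simulated_trees(12, seed=71):
            n_paths = count_genealogies(tree)
            if n_paths <= 10_000:
                assert n_paths == sum(1 for _ in enumerate_genealogies(tree))

    def test_enumeration_matches_count_and_order(self):
        for _, tree in small_simulated_trees(12, seed=83):
            configs = list(enumerate_configurations(tree))
            assert len(configs) == count_configurations(tree)
            seq = [(c.level, c.canonical_key(True)) for c in configs]
            assert seq == sorted(seq, key=lambda lk: (-lk[0], lk[1]))
            assert len(set(k for _, k in seq)) == len(seq)

    def test_genealogy_cap_signals(self):
        with pytest.raises(CapExceededError):
            list(enumerate_genealogies(two_private_tree(), cap=1))


class TestProfile:
    def test_mrca_profile(self, mrca_tree):
        assert profile_levels(mrca_tree).counts == {1: 1}

    def test_one_mutation_profile(self):
        assert profile_levels(one_mutation_tree()).counts == {3: 1, 2: 1, 1: 1}

    def test_profile_sums_to_configuration_count(self):
        for _, tree in small_simulated_trees(12, seed=97):
            profile = profile_levels(tree)
            assert profile.total == count_configurations(tree)
            assert sorted(profile.counts) == list(
                range(1, tree.level + 1)
            )
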