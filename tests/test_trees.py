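import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from selscape.errors import InvalidArgumentError
from selscape.synthetic import random_tree
from selscape.trees import (
    Phylogeny,
    compare_subtree_constraints,
    extract_subtrees,
    find_split_branch,
    flag_unreliable_subtree,
    phylogenetic_depth,
)


def brute_force_depth(tree: Phylogeny) -> float:
    """Exhaustive path-sum oracle for root-to-tip depth."""
    best = 0.0
    for tip in tree.tips():
        node, total = tip, 0.0
        while node.parent is not None:
            total += node.length
            node = node.parent
        best = max(best, total)
    return best


def brute_force_split(tree: Phylogeny, min_tips: int, min_depth: float):
    """Exhaustive edge-scan oracle: returns the best (key, branch label)."""
    depths = tree.node_depths()
    all_tips = set(tree.tip_labels)
    best = None
    order = 0
    for node in tree.preorder():
        if node.parent is None:
            continue
        order += 1
        tips_a = {t.label for t in _tips_below(node)}
        tips_b = all_tips - tips_a
        if len(tips_a) < min_tips or len(tips_b) < min_tips:
            continue
        depth_a = max(depths[t] for t in tips_a) - depths[node.label]
        depth_b = max(depths[t] for t in tips_b)
        if depth_a <= min_depth or depth_b <= min_depth:
            continue
        key = (min(len(tips_a), len(tips_b)), -order)
        if best is None or key > best[0]:
            best = (key, node.label)
    return best


def _tips_below(node):
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


class TestPhylogeny:
    def test_newick_roundtrip(self, quartet_tree):
        again = Phylogeny.from_newick(quartet_tree.to_newick())
        assert again.to_newick() == quartet_tree.to_newick()
        assert again.tip_labels == ["A", "B", "C", "D"]

    def test_total_length(self, quartet_tree):
        assert quartet_tree.total_length() == pytest.approx(1.0)

    def test_single_tip_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Phylogeny.from_newick("(A:1.0);")

    def test_negative_length_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Phylogeny.from_newick("(A:1.0,B:-0.5)R;")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Phylogeny.from_newick("(A:1.0,A:0.5)R;")

    def test_internal_labels_assigned(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:1);")
        labels = tree.node_labels()
        assert len(labels) == len(set(labels))
        assert all(lbl is not None for lbl in labels)


class TestDepth:
    def test_two_tip_max_path(self, two_tip_tree):
        assert phylogenetic_depth(two_tip_tree) == pytest.approx(0.3)

    def test_zero_lengths(self):
        tree = Phylogeny.from_newick("(A:0,B:0)R;")
        assert phylogenetic_depth(tree) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_path_oracle(self, seed):
        tree = random_tree(20, 2.0, seed)
        assert phylogenetic_depth(tree) == pytest.approx(
            brute_force_depth(tree), abs=1e-12
        )

    def test_monotone_in_deepest_edge(self):
        tree = random_tree(15, 1.0, 3)
        before = phylogenetic_depth(tree)
        depths = tree.node_depths()
        deepest = max(tree.tips(), key=lambda t: depths[t.label])
        deepest.length += 0.5
        assert phylogenetic_depth(Phylogeny(tree.root)) == pytest.approx(
            before + 0.5
        )


class TestFindSplitBranch:
    def test_thirty_tips_cannot_split(self):
        tree = random_tree(30, 5.0, 1)
        assert find_split_branch(tree, min_tips=20, min_depth=0.0) is None

    def test_balanced_fixture(self):
        left = ",".join(f"a{i}:0.3" for i in range(25))
        right = ",".join(f"b{i}:0.3" for i in range(25))
        nwk = f"(({left})L:0.5,({right})M:0.5)R;"
        tree = Phylogeny.from_newick(nwk)
        split = find_split_branch(tree, min_tips=20, min_depth=0.2)
        assert split is not None
        assert {len(split.tips_a), len(split.tips_b)} == {25}
        assert split.depth_a == pytest.approx(0.3)
        # remainder keeps the root, so its depth includes the 0.5 stem
        assert split.depth_b == pytest.approx(0.8)

    def test_max_min_tie_break(self):
        # caterpillar-ish tree offering 20/25 and 22/23 partitions
        def clade(prefix, n):
            return "(" + ",".join(f"{prefix}{i}:0.5" for i in range(n)) + ")"

        # topology: ((20)(2)(23)): edge under the 20-clade gives 20/25;
        # edge above (20+2) gives 22/23.
        nwk = (
            f"(({clade('a', 20)}A:0.5,{clade('b', 2)}B:0.5)AB:0.5,"
            f"{clade('c', 23)}C:0.5)R;"
        )
        tree = Phylogeny.from_newick(nwk)
        split = find_split_branch(tree, min_tips=20, min_depth=0.2)
        assert split is not None
        assert sorted([len(split.tips_a), len(split.tips_b)]) == [22, 23]
        assert split.branch_id == "AB"

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 61))
        tree = random_tree(n, float(rng.uniform(1.0, 6.0)), seed + 1000)
        result = find_split_branch(tree, min_tips=15, min_depth=0.05)
        oracle = brute_force_split(tree, min_tips=15, min_depth=0.05)
        if oracle is None:
            assert result is None
        else:
            assert result is not None
            assert result.branch_id == oracle[1]

    @settings(max_examples=20, deadline=None)
    @given(seed=hst.integers(0, 10_000), n=hst.integers(10, 60))
    def test_property_agreement_random_trees(self, seed, n):
        tree = random_tree(n, 3.0, seed)
        result = find_split_branch(tree, min_tips=5, min_depth=0.01)
        oracle = brute_force_split(tree, min_tips=5, min_depth=0.01)
        if oracle is None:
            assert result is None
        else:
            assert result.branch_id == oracle[1]


class TestExtractSubtrees:
    def test_partition_and_conservation(self):
        tree = random_tree(50, 4.0, 9)
        split = find_split_branch(tree, min_tips=10, min_depth=0.01)
        assert split is not None
        removed_edge = tree.find(split.branch_id).length
        sub_a, sub_b = extract_subtrees(tree, split)
        assert set(sub_a.tip_labels) == set(split.tips_a)
        assert set(sub_b.tip_labels) == set(split.tips_b)
        assert sub_a.total_length() + sub_b.total_length() + removed_edge == (
            pytest.approx(tree.total_length())
        )

    def test_depths_match_candidate(self):
        tree = random_tree(40, 3.0, 21)
        split = find_split_branch(tree, min_tips=8, min_depth=0.01)
        assert split is not None
        sub_a, sub_b = extract_subtrees(tree, split)
        assert phylogenetic_depth(sub_a) == pytest.approx(split.depth_a)
        assert phylogenetic_depth(sub_b) == pytest.approx(split.depth_b)

    def test_stale_split_rejected(self):
        tree = random_tree(40, 3.0, 5)
        split = find_split_branch(tree, min_tips=8, min_depth=0.01)
        other = random_tree(40, 3.0, 6)
        with pytest.raises(InvalidArgumentError):
            extract_subtrees(other, split)


class TestFlagUnreliableSubtree:
    def test_just_above_threshold(self):
        values = [1.0] * 31 + [0.5] * 69
        assert flag_unreliable_subtree(values) is True

    def test_exactly_at_threshold_not_flagged(self):
        values = [1.0] * 30 + [0.5] * 70
        assert flag_unreliable_subtree(values) is False

    def test_no_boundary_values(self):
        assert flag_unreliable_subtree([0.2, 0.5, 0.9]) is False

    def test_tolerance_on_boundary(self):
        assert flag_unreliable_subtree([1.0 + 5e-7] * 10 + [0.5] * 10) is True

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            flag_unreliable_subtree([])


class TestCompareSubtreeConstraints:
    def test_equal_factors(self):
        measure, flagged = compare_subtree_constraints(0.3, 0.3)
        assert measure == 0.0 and not flagged

    def test_fifty_percent_difference_flagged(self):
        f_a, f_b = math.log(1.5), 0.0
        measure, flagged = compare_subtree_constraints(f_a, f_b)
        assert measure == pytest.approx(0.5)
        assert flagged

    def test_forty_percent_not_flagged(self):
        f_a, f_b = math.log(1.4), 0.0
        measure, flagged = compare_subtree_constraints(f_a, f_b)
        assert measure == pytest.approx(0.4)
        assert not flagged

    def test_symmetric(self):
        m1, _ = compare_subtree_constraints(0.1, 0.9)
        m2, _ = compare_subtree_constraints(0.9, 0.1)
        assert m1 == pytest.approx(m2)


@pytest.fixture(scope="module")
def setup():
    from selscape.codon import CodonModelParams, simulate_alignment

    tree = random_tree(8, 1.0, 31)
    aln = simulate_alignment(tree, CodonModelParams(0.3, 2.0), 120, seed=2)
    split = find_split_branch(tree, min_tips=3, min_depth=0.01)
    assert split is not None
    sub_a, _ = extract_subtrees(tree, split)
    return aln, sub_a


class TestBootstrapSubtreeDnds:
    def test_zero_reference_gives_one(self, setup):
        from selscape.trees import bootstrap_subtree_dnds

        aln, sub = setup
        result = bootstrap_subtree_dnds(aln, sub, 0.0, n_replicates=5, seed=1)
        assert result.proportion == 1.0

    def test_infinite_reference_gives_zero(self, setup):
        from selscape.trees import bootstrap_subtree_dnds

        aln, sub = setup
        result = bootstrap_subtree_dnds(
            aln, sub, math.inf, n_replicates=5, seed=1
        )
        assert result.proportion == 0.0

    def test_column_order_invariance(self, setup):
        from selscape.trees import bootstrap_subtree_dnds

        aln, sub = setup
        rng = np.random.default_rng(5)
        perm = rng.permutation(aln.length_codons)
        shuffled = aln.take_codon_columns(perm)
        a = bootstrap_subtree_dnds(aln, sub, 0.3, n_replicates=4, seed=2)
        b = bootstrap_subtree_dnds(shuffled, sub, 0.3, n_replicates=4, seed=2)
        assert a == b

    def test_missing_taxa_rejected(self, setup):
        from selscape.codon import CodonAlignment
        from selscape.trees import bootstrap_subtree_dnds

        _, sub = setup
        tiny = CodonAlignment(("zz1", "zz2"), ("ATGGCT", "ATGGCA"))
        with pytest.raises(InvalidArgumentError):
            bootstrap_subtree_dnds(tiny, sub, 0.3, n_replicates=2, seed=0)
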