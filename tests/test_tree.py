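"""Tree structure, Newick round trips, and the node-algebra operations."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from treelink import NewickParseError, Tree, ValidationError, parse_newick, write_newick
from treelink.fixtures import random_tree

from conftest import (
    bf_descendants,
    bf_share,
    bf_union_leaf,
    edges_of,
)


class TestParseAndNumbering:
    def test_col_fixture_numbering(self, col_tree):
        assert col_tree.n_tips == 4
        assert col_tree.root == 5
        assert col_tree.resolve("GroupA") == 6
        assert col_tree.resolve("GroupB") == 7
        assert col_tree.tip_labels == ["sample1", "sample2", "sample3", "sample4"]

    def test_trivial_two_tip_tree(self):
        t = parse_newick("(a,b);")
        assert t.n_tips == 2
        assert t.resolve("a") == 1 and t.resolve("b") == 2
        assert t.root == 3
        assert t.internal_labels == [None]

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_round_trip_random_trees(self, n, seed):
        t = random_tree(n, seed)
        text = write_newick(t)
        back = parse_newick(text)
        assert back._children == t._children
        assert back.tip_labels == t.tip_labels
        assert back.internal_labels == t.internal_labels
        for v, length in t.branch_lengths.items():
            assert back.branch_lengths[v] == pytest.approx(length, rel=1e-11)
        # serialization of the re-parsed tree is byte-identical
        assert write_newick(back) == text

    def test_reparse_reproduces_numbering(self, row_tree):
        back = parse_newick(write_newick(row_tree))
        for v in range(1, row_tree.n_nodes + 1):
            assert back.label(v) == row_tree.label(v)

    @pytest.mark.parametrize("bad", ["((a,b);", "(a,b));", "(a,b)", "('x,y);"])
    def test_malformed_newick(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError):
            parse_newick("(a,a);")
        with pytest.raises(ValidationError):
            parse_newick("((a,b)x,(c,d)x);")

    def test_branch_lengths_precision(self):
        t = parse_newick("(a:0.123456789012,b:3.0):0.5;")
        back = parse_newick(write_newick(t))
        assert back.branch_lengths == t.branch_lengths


class TestConvertNode:
    def test_labels_to_numbers(self, col_tree, row_tree):
        assert col_tree.convert_node(["GroupA", "GroupB"], to="number") == [6, 7]
        assert row_tree.convert_node(["t3"], to="number") == [1]

    def test_empty_and_identity(self, col_tree):
        assert col_tree.convert_node([], to="number") == []
        nums = [1, 6, 7]
        labs = col_tree.convert_node(nums, to="label")
        assert col_tree.convert_node(labs, to="number") == nums

    def test_unlabeled_internal_converts_to_none(self, row_tree):
        assert row_tree.convert_node([6], to="label") == [None]

    def test_unknown_reference_named_in_error(self, col_tree):
        with pytest.raises(Exception, match="zzz"):
            col_tree.convert_node(["zzz"], to="number")


class TestDescendantsAndRelatives:
    def test_fixture_examples(self, col_tree, row_tree):
        assert col_tree.find_descendant(6, only_leaf=True) == [1, 2]
        assert row_tree.find_descendant(8, only_leaf=False) == [3, 4, 5, 9]
        assert col_tree.find_descendant(1, only_leaf=True, self_include=True) == [1]

    def test_child_ancestor_sibling(self, col_tree):
        assert col_tree.find_child(5) == [6, 7]
        assert col_tree.find_ancestor(1, 1) == 6
        assert col_tree.find_ancestor(1, 2) == 5
        assert col_tree.find_sibling(1) == [2]
        assert col_tree.find_sibling(5) == []
        with pytest.raises(ValidationError):
            col_tree.find_ancestor(1, 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_descendants_equal_brute_force(self, seed):
        t = random_tree(2 + seed % 9, seed)
        edges = edges_of(t)
        tips = set(range(1, t.n_tips + 1))
        for v in range(1, t.n_nodes + 1):
            expect = bf_descendants(edges, v, tips)
            assert t.find_descendant(v) == sorted(expect)
            assert t.find_descendant(v, only_leaf=True) == sorted(expect & tips)


class TestShareUnionJoin:
    def test_share_examples(self, col_tree, row_tree):
        assert col_tree.share_node(["sample1", "sample2"]) == 6
        assert row_tree.share_node(["t1", "t4"]) == 8
        assert col_tree.share_node(["GroupA"]) == 6

    def test_share_empty_errors(self, col_tree):
        with pytest.raises(ValueError):
            col_tree.share_node([])

    def test_union_leaf_examples(self, col_tree, row_tree):
        assert row_tree.union_leaf([7, 4]) == [1, 2, 4]
        assert col_tree.union_leaf([5]) == [1, 2, 3, 4]
        tips = list(range(1, col_tree.n_tips + 1))
        assert col_tree.union_leaf(tips) == tips

    def test_join_examples(self, col_tree, row_tree):
        assert row_tree.join_node([3, 4, 5]) == [8]
        assert row_tree.join_node([1, 3]) == [1, 3]
        assert col_tree.join_node([1, 2, 3, 4]) == [5]

    @pytest.mark.parametrize("seed", range(15))
    def test_share_and_join_against_oracles(self, seed):
        t = random_tree(2 + seed % 9, seed)
        edges = edges_of(t)
        tips = set(range(1, t.n_tips + 1))
        import random

        rng = random.Random(seed)
        for _ in range(10):
            k = rng.randint(1, t.n_nodes)
            nodes = rng.sample(range(1, t.n_nodes + 1), k)
            assert t.share_node(nodes) == bf_share(edges, nodes)
            assert t.union_leaf(nodes) == bf_union_leaf(edges, nodes, tips)
            joined = t.join_node(nodes)
            # leaf union preserved exactly
            assert t.union_leaf(joined) == t.union_leaf(nodes)
            # minimal: no complete sibling set remains
            s = set(joined)
            for v in range(t.n_tips + 1, t.n_nodes + 1):
                ch = set(t.find_child(v))
                assert not (ch and ch <= s and v not in s)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_share_node_associative_over_extension(self, seed):
        import random

        t = random_tree(2 + seed % 9, seed)
        rng = random.Random(seed)
        nodes = [rng.randint(1, t.n_nodes) for _ in range(3)]
        assert t.share_node(nodes) == t.share_node(
            [t.share_node(nodes[:2]), nodes[2]]
        )


class TestDistAndPaths:
    def test_dist_unit_lengths(self, col_tree):
        assert col_tree.dist_node(1, 2) == 2
        assert col_tree.dist_node(1, 3) == 4
        assert col_tree.dist_node("GroupA", "GroupA") == 0

    def test_dist_with_branch_lengths(self):
        t = parse_newick("((a:1.5,b:2.5)x:3,c:4);")
        assert t.dist_node("a", "b") == 4.0
        assert t.dist_node("a", "c") == 8.5

    def test_mat_tree_fixture(self, col_tree):
        m = col_tree.mat_tree()
        assert m.values.tolist() == [[1, 6, 5], [2, 6, 5], [3, 7, 5], [4, 7, 5]]

    def test_mat_tree_single_split(self):
        m = parse_newick("(a,b);").mat_tree()
        assert m.values.tolist() == [[1, 3], [2, 3]]

    @pytest.mark.parametrize("seed", range(10))
    def test_mat_tree_row_count_and_padding(self, seed):
        t = random_tree(2 + seed, seed)
        m = t.mat_tree()
        assert len(m) == t.n_tips
        for tip in range(1, t.n_tips + 1):
            path = [v for v in m.iloc[tip - 1] if v is not pd.NA]
            assert path[0] == tip and path[-1] == t.root


class TestNodeInfo:
    def test_count_show_isleaf(self, col_tree):
        assert col_tree.count_node() == 7
        assert col_tree.is_leaf([1, 6]) == [True, False]
        assert col_tree.show_node() == list(range(1, 8))
        assert col_tree.show_node(only_leaf=True) == [1, 2, 3, 4]

    def test_show_node_taxonomy_tree(self, taxa_tree):
        assert len(taxa_tree.show_node(only_leaf=False)) == 12

    def test_count_node_bifurcating_iff(self):
        bif = random_tree(6, 3)
        assert bif.count_node() == 2 * bif.n_tips - 1
        multi = parse_newick("(a,b,c);")
        assert multi.count_node() != 2 * multi.n_tips - 1

    def test_print_node(self, col_tree):
        tab = col_tree.print_node("leaf")
        assert list(tab["nodeLab"]) == ["sample1", "sample2", "sample3", "sample4"]
        assert list(tab["isLeaf"]) == [True] * 4
        internal = col_tree.print_node("internal")
        assert list(internal["nodeNum"]) == [5, 6, 7]


class TestLabeling:
    def test_add_label_internal_format(self, row_tree):
        labeled = row_tree.add_label("internal")
        assert [labeled.label(v) for v in range(6, 10)] == [
            "Node_6", "Node_7", "Node_8", "Node_9",
        ]

    def test_add_label_no_op_on_labeled_tree(self, col_tree):
        assert col_tree.add_label("internal") == col_tree

    @pytest.mark.parametrize("seed", range(10))
    def test_add_label_keeps_labels_unique(self, seed):
        t = random_tree(3 + seed, seed).add_label("all")
        labels = [t.label(v) for v in range(1, t.n_nodes + 1)]
        assert len(set(labels)) == len(labels)

    def test_track_node_aliases(self, col_tree):
        tracked = col_tree.track_node()
        assert tracked.label(6) == "alias_6"
        assert tracked.convert_node(["alias_1", "alias_7"], to="number") == [1, 7]


class TestPruning:
    def test_keep_tips_fixture(self, row_tree):
        pruned = row_tree.keep_tips(["t2", "t3"])
        assert pruned.n_tips == 2
        assert set(pruned.tip_labels) == {"t2", "t3"}

    def test_keep_all_tips_identity_topology(self, col_tree):
        pruned = col_tree.keep_tips(list(range(1, 5)))
        assert pruned == col_tree

    def test_keep_tips_errors(self, col_tree):
        with pytest.raises(ValidationError):
            col_tree.keep_tips([])
        with pytest.raises(ValidationError):
            col_tree.keep_tips(["GroupA"])

    def test_keep_tips_sums_suppressed_lengths(self):
        t = parse_newick("((a:1,b:2)x:3,c:4);")
        pruned = t.keep_tips(["a", "c"])
        # x became unary and was suppressed: a's edge is 1 + 3
        assert pruned.branch_lengths[pruned.resolve("a")] == 4.0

    @pytest.mark.parametrize("seed", range(20))
    def test_keep_tips_tip_set(self, seed):
        import random

        t = random_tree(3 + seed % 8, seed)
        rng = random.Random(seed)
        keep = rng.sample(range(1, t.n_tips + 1), rng.randint(1, t.n_tips))
        pruned = t.keep_tips(keep)
        assert set(pruned.tip_labels) == {t.label(v) for v in keep}

    @pytest.mark.parametrize("seed", range(20))
    def test_track_then_prune_recovers_nodes(self, seed):
        """Alias labels recover each retained node across renumbering, and
        the correspondence equals a brute-force label search."""
        import random

        t = random_tree(4 + seed % 7, seed)
        rng = random.Random(seed)
        keep = rng.sample(range(1, t.n_tips + 1), rng.randint(2, t.n_tips))
        tracked = t.track_node().keep_tips(keep)
        by_label = {
            tracked.label(v): v for v in range(1, tracked.n_nodes + 1)
        }
        for old in range(1, t.n_nodes + 1):
            alias = f"alias_{old}"
            if alias in by_label:
                assert tracked.resolve(alias) == by_label[alias]

    def test_tracked_prune_root_example(self, col_tree):
        tracked = col_tree.track_node().keep_tips([1, 2])
        assert tracked.label(tracked.root) == "alias_6"


class TestAsLeaf:
    def test_as_leaf_taxonomy(self, taxa_tree):
        out = taxa_tree.as_leaf(["Class:C3"])
        assert out.n_tips == 5
        assert set(out.tip_labels) == {"D1", "D2", "D3", "D4", "Class:C3"}

    def test_as_leaf_counts_on_binary_tree(self):
        t = random_tree(49, 7).add_label("internal")
        # three disjoint clades
        picks = []
        sizes = []
        for v in range(t.n_tips + 1, t.n_nodes + 1):
            tips_below = t.find_descendant(v, only_leaf=True)
            if 2 <= len(tips_below) <= 6:
                if all(
                    not set(tips_below) & set(t.find_descendant(p, only_leaf=True))
                    for p in picks
                ):
                    picks.append(v)
                    sizes.append(len(tips_below))
            if len(picks) == 3:
                break
        assert len(picks) == 3
        out = t.as_leaf(picks)
        assert out.n_tips == 49 - sum(sizes) + 3

    def test_as_leaf_empty_identity(self, col_tree):
        assert col_tree.as_leaf([]) == col_tree

    def test_as_leaf_rejects_nested_nodes(self, taxa_tree):
        with pytest.raises(ValidationError):
            taxa_tree.as_leaf(["Phylum:B2", "Class:C3"])
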