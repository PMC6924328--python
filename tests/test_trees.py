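"""Neighbor joining, bootstrap supports, tree distances, newick IO."""

import numpy as np
import pandas as pd
import pytest

import chemosignal as cs
from chemosignal.trees import tip_bipartitions

from _oracles import euclidean_bruteforce, patristic_bruteforce
from conftest import random_additive_tree


class TestProfileDistance:
    def test_identical_rows_distance_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert cs.profile_distance(m).values[0, 1] == 0.0

    def test_pythagorean_case(self):
        m = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        assert cs.profile_distance(m).values[0, 1] == pytest.approx(5.0)

    def test_matches_bruteforce_sum_of_squares(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.uniform(0, 10, (5, 4)), index=list("abcde"))
        np.testing.assert_allclose(
            cs.profile_distance(m).values, euclidean_bruteforce(m.values), atol=1e-12
        )

    def test_triangle_inequality_on_random_fixtures(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = pd.DataFrame(rng.uniform(0, 5, (6, 8)),
                             index=[f"s{i}" for i in range(6)])
            d = cs.profile_distance(m).values
            for i in range(6):
                for j in range(6):
                    for k in range(6):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_nonfinite_rejected(self):
        m = pd.DataFrame([[np.nan, 1.0], [0.0, 1.0]], index=["a", "b"])
        with pytest.raises(ValueError, match="non-finite"):
            cs.profile_distance(m)


class TestNeighborJoining:
    def test_three_taxon_pendant_lengths(self, three_taxon_dm):
        tree = cs.neighbor_joining(three_taxon_dm)
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_recovers_additive_six_tip_tree(self):
        true_tree = random_additive_tree(99, n_min=6, n_max=7)
        d = cs.patristic_distances(true_tree)
        rebuilt = cs.neighbor_joining(d)
        assert tip_bipartitions(rebuilt) == tip_bipartitions(true_tree)
        np.testing.assert_allclose(
            cs.patristic_distances(rebuilt).values, d.values, atol=1e-9
        )

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        tree = random_additive_tree(4, n_min=7, n_max=8)
        d = cs.patristic_distances(tree)
        perm = rng.permutation(d.n)
        shuffled = cs.DistanceMatrix(
            tuple(d.labels[i] for i in perm), d.values[np.ix_(perm, perm)]
        )
        assert tip_bipartitions(cs.neighbor_joining(d)) == tip_bipartitions(
            cs.neighbor_joining(shuffled)
        )

    def test_matches_skbio_topology_on_noisy_matrix(self):
        # independent implementation cross-check on a non-additive matrix
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(8)
        tree = random_additive_tree(8, n_min=8, n_max=9)
        d = cs.patristic_distances(tree)
        noisy = d.values + rng.uniform(0, 0.02, d.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        dm = cs.DistanceMatrix(d.labels, noisy)
        ours = cs.neighbor_joining(dm)
        theirs_sk = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=list(d.labels)))
        theirs = cs.read_newick(str(theirs_sk).strip())
        assert tip_bipartitions(ours) == tip_bipartitions(theirs)

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            cs.neighbor_joining(
                cs.DistanceMatrix(("a", "b"), np.array([[0.0, 1], [1, 0]]))
            )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            cs.DistanceMatrix(("a", "b", "c"),
                              np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]]))


class TestBootstrapSupport:
    def test_identical_columns_give_full_support(self):
        # every compound column identical: any resample reproduces the same
        # matrix, so every replicate yields the same tree
        col = np.array([0.0, 1.0, 3.0, 7.0, 15.0, 31.0])
        m = pd.DataFrame(np.tile(col[:, None], (1, 8)),
                         index=[f"s{i}" for i in range(6)])
        result = cs.bootstrap_support(m, b=20, seed=0)
        supports = [int(n.label) for n in result.preorder_internal_node_iter()
                    if n.label is not None]
        assert supports and all(s == 20 for s in supports)

    def test_zero_iterations_rejected(self):
        m = pd.DataFrame(np.eye(4), index=list("abcd"))
        with pytest.raises(ValueError, match=">= 1"):
            cs.bootstrap_support(m, b=0)

    def test_clean_clusters_get_high_support(self):
        # two tight clusters separated far beyond within-cluster noise
        rng = np.random.default_rng(5)
        base = np.vstack([np.zeros((4, 6)), np.full((4, 6), 50.0)])
        m = pd.DataFrame(base + rng.normal(0, 0.5, base.shape),
                         index=[f"s{i}" for i in range(8)])
        result = cs.bootstrap_support(m, b=100, seed=1)
        cluster = frozenset(f"s{i}" for i in range(4, 8))
        tips = frozenset(f"s{i}" for i in range(8))
        supports = {}
        for n in result.preorder_internal_node_iter():
            if n.label is None:
                continue
            below = frozenset(l.taxon.label for l in n.leaf_iter())
            # bipartitions are unordered: key by the side not holding s0
            side = tips - below if "s0" in below else below
            supports[side] = int(n.label)
        assert supports.get(cluster, 0) >= 95

    def test_reproducible_with_same_seed(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.uniform(0, 3, (6, 10)),
                         index=[f"s{i}" for i in range(6)])
        a = cs.write_newick(cs.bootstrap_support(m, b=30, seed=7))
        b = cs.write_newick(cs.bootstrap_support(m, b=30, seed=7))
        assert a == b


class TestTreeDistances:
    def test_three_taxon_path_sum(self, three_taxon_dm):
        tree = cs.neighbor_joining(three_taxon_dm)
        assert cs.patristic_distances(tree).row("A")["C"] == pytest.approx(4.0)

    def test_patristic_matches_bruteforce_paths(self):
        tree = random_additive_tree(33, n_min=5, n_max=12)
        labels, expected = patristic_bruteforce(tree)
        got = cs.patristic_distances(tree)
        np.testing.assert_allclose(
            got.submatrix(labels).values, expected, atol=1e-12
        )

    def test_distance_to_reference_excludes_self(self, three_taxon_dm):
        tree = cs.neighbor_joining(three_taxon_dm)
        row = cs.distance_to_reference(tree, "A")
        assert "A" not in row.index
        assert set(row.index) == {"B", "C"}

    def test_unknown_reference_error_lists_labels(self, three_taxon_dm):
        with pytest.raises(KeyError, match="available.*A"):
            cs.distance_to_reference(three_taxon_dm, "Z")


class TestPruneTips:
    def test_keep_all_is_identity(self):
        tree = random_additive_tree(12, n_min=6, n_max=7)
        keep = [l.taxon.label for l in tree.leaf_node_iter()]
        pruned = cs.prune_tips(tree, keep)
        np.testing.assert_allclose(
            cs.patristic_distances(pruned).values,
            cs.patristic_distances(tree).values, atol=1e-12,
        )

    def test_path_lengths_conserved_for_retained_pairs(self):
        tree = random_additive_tree(55, n_min=6, n_max=9)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        keep = labels[1:]
        before = cs.patristic_distances(tree).submatrix(keep)
        after = cs.patristic_distances(cs.prune_tips(tree, keep)).submatrix(keep)
        np.testing.assert_allclose(after.values, before.values, atol=1e-9)

    def test_too_small_keep_set_rejected(self, balanced_tree):
        with pytest.raises(ValueError, match=">= 3"):
            cs.prune_tips(balanced_tree, ["A", "B"])


class TestNewickIO:
    def test_simple_tree_roundtrips_byte_identically(self):
        text = "(A:1,B:1,C:3);"
        assert cs.write_newick(cs.read_newick(text)) == text

    def test_random_trees_roundtrip(self):
        for seed in range(30):
            tree = random_additive_tree(seed)
            text = cs.write_newick(tree)
            again = cs.write_newick(cs.read_newick(text))
            assert text == again
            np.testing.assert_allclose(
                cs.patristic_distances(cs.read_newick(text)).values,
                cs.patristic_distances(tree).values, atol=1e-12,
            )

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cs.read_newick("(A:1,(A:1,B:1):1);")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            cs.read_newick("((A:1,B:1):1;")

    def test_asymmetric_distance_csv_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(",a,b\na,0,1\nb,2,0\n")
        with pytest.raises(ValueError, match="asymmetric"):
            cs.trees.read_distance_csv(path)

    def test_non_square_distance_csv_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(",a,b\na,0,1\nc,1,0\n")
        with pytest.raises(ValueError, match="square"):
            cs.trees.read_distance_csv(path)


class TestClampNegativeLengths:
    def test_root_to_tip_depths_preserved_for_internal_negatives(self):
        tree = cs.read_newick("((A:2,B:3):-1,(C:1,D:1):2);")
        clamped = cs.trees.clamp_negative_branch_lengths(tree)
        from _oracles import vcv_bruteforce

        _, v_before = vcv_bruteforce(tree)
        _, v_after = vcv_bruteforce(clamped)
        np.testing.assert_allclose(np.diag(v_after), np.diag(v_before), atol=1e-12)
        assert all(
            (n.edge.length or 0) >= 0
            for n in clamped.preorder_node_iter() if n.parent_node is not None
        )
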