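"""Ward.D2 clustering, Newick serialization, bootstrap support and ARI."""


import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

import vafclust as vc
from conftest import (
    distance_matrix_from_array,
    make_vaf_matrix,
    naive_ward,
    random_distance_matrix,
)


class TestWardCluster:
    def test_two_samples_merge_at_their_distance(self):
        dm = distance_matrix_from_array([[0.0, 0.4], [0.4, 0.0]], ["A", "B"])
        tree = vc.ward_cluster(dm)
        assert tree.merges == [(0, 1, pytest.approx(0.4), 2)]

    def test_three_point_hand_arithmetic(self):
        """d(1,2)=0.1, d(1,3)=d(2,3)=1: first merge at 0.1, second at
        sqrt((2*1 + 2*1 - 0.01)/3) per the Lance-Williams update."""
        d = np.array([[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]])
        tree = vc.ward_cluster(distance_matrix_from_array(d))
        (a1, b1, h1, s1), (a2, b2, h2, s2) = tree.merges
        assert (a1, b1, s1) == (0, 1, 2)
        assert h1 == pytest.approx(0.1, abs=1e-15)
        assert (a2, b2, s2) == (2, 3, 3)
        assert h2 == pytest.approx(np.sqrt(3.99 / 3.0), abs=1e-12)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_naive_per_step_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        d = random_distance_matrix(rng, n)
        tree = vc.ward_cluster(distance_matrix_from_array(d))
        expected = naive_ward(d)
        for (a, b, h, s), (ea, eb, eh, es) in zip(tree.merges, expected):
            assert (a, b, s) == (ea, eb, es)
            assert h == pytest.approx(eh, abs=1e-10)

    @pytest.mark.parametrize("seed", range(15))
    def test_heights_match_scipy_ward_linkage(self, seed):
        """scipy's ward on a condensed distance matrix follows the same
        ward.D2 convention; heights must agree (topology may differ only on
        exact ties, absent in random instances)."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(4, 12))
        d = random_distance_matrix(rng, n)
        tree = vc.ward_cluster(distance_matrix_from_array(d))
        Z = linkage(squareform(d, checks=False), method="ward")
        assert np.allclose([m[2] for m in tree.merges], Z[:, 2], atol=1e-10)

    def test_heights_are_monotone_nondecreasing(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            d = random_distance_matrix(rng, int(rng.integers(4, 15)))
            tree = vc.ward_cluster(distance_matrix_from_array(d))
            heights = [m[2] for m in tree.merges]
            assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_refuses_undefined_pairs_and_tiny_input(self):
        dm = distance_matrix_from_array(np.zeros((3, 3)))
        dm.d[0, 1] = dm.d[1, 0] = np.nan
        dm.defined[0, 1] = dm.defined[1, 0] = False
        with pytest.raises(ValueError, match="undefined"):
            vc.ward_cluster(dm)
        with pytest.raises(ValueError, match="at least 2"):
            vc.ward_cluster(distance_matrix_from_array(np.zeros((1, 1))))


class TestNewick:
    def test_two_leaf_tree(self):
        dm = distance_matrix_from_array([[0.0, 0.4], [0.4, 0.0]], ["A", "B"])
        assert vc.to_newick(vc.ward_cluster(dm)) == "(A:0.4,B:0.4);"

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_preserves_clades_and_heights(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        names = [f"leaf{i}" for i in range(n)]
        tree = vc.ward_cluster(
            distance_matrix_from_array(random_distance_matrix(rng, n), names)
        )
        text = vc.to_newick(tree)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        parsed_clades = {
            frozenset(l.taxon.label for l in node.leaf_iter())
            for node in parsed.preorder_node_iter()
            if not node.is_leaf() and node.parent_node is not None
        }
        assert parsed_clades == set(tree.clades())
        # ultrametric: root-to-leaf path length equals the final merge height
        parsed.calc_node_root_distances()
        root_height = tree.merges[-1][2]
        for leaf in parsed.leaf_node_iter():
            assert leaf.root_distance == pytest.approx(root_height, abs=1e-9)

    def test_awkward_names_are_quoted_and_reparseable(self):
        names = ["has space", "colon:name", "par(en", "quo'te"]
        rng = np.random.default_rng(0)
        tree = vc.ward_cluster(
            distance_matrix_from_array(random_distance_matrix(rng, 4), names)
        )
        text = vc.to_newick(tree)
        parsed = dendropy.Tree.get(data=text, schema="newick",
                                   preserve_underscores=True)
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(names)


class TestBootstrap:
    def test_identical_columns_give_full_support(self):
        """Columns are copies of one pattern separating two groups:
        resampling cannot change anything, so both group clades get 1.0."""
        col = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        vaf = np.tile(col[:, None], (1, 30))
        # perturb within groups so within-group structure exists but is tiny
        vaf[1, :] += 0.01
        vaf[4, :] -= 0.01
        mat = make_vaf_matrix(vaf, np.full((6, 30), 30.0))
        res = vc.bootstrap_support(mat, B=25, seed=0)
        g1 = frozenset(["s0", "s1", "s2"])
        g2 = frozenset(["s3", "s4", "s5"])
        assert res.support[g1] == 1.0
        assert res.support[g2] == 1.0

    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(1)
        mat = make_vaf_matrix(
            rng.uniform(size=(5, 40)), np.full((5, 40), 30.0)
        )
        res = vc.bootstrap_support(mat, B=1, seed=0)
        assert set(res.support.values()) <= {0.0, 1.0}
        assert res.n_replicates == 1

    def test_same_seed_reproduces_result(self, strong_vaf_matrix):
        _, mat = strong_vaf_matrix
        a = vc.bootstrap_support(mat, B=20, seed=9)
        b = vc.bootstrap_support(mat, B=20, seed=9)
        assert a.support == b.support

    def test_supports_invariant_to_leaf_relabeling(self):
        rng = np.random.default_rng(7)
        vaf = rng.uniform(size=(6, 60))
        depth = np.full((6, 60), 30.0)
        base = vc.bootstrap_support(make_vaf_matrix(vaf, depth), B=15, seed=3)
        renames = {f"s{i}": f"renamed_{i}" for i in range(6)}
        relabeled = vc.bootstrap_support(
            make_vaf_matrix(vaf, depth, samples=[renames[f"s{i}"] for i in range(6)]),
            B=15, seed=3,
        )
        mapped = {
            frozenset(renames[x] for x in clade): v for clade, v in base.support.items()
        }
        assert mapped == relabeled.support

    def test_trivial_clades_excluded(self):
        rng = np.random.default_rng(2)
        mat = make_vaf_matrix(rng.uniform(size=(5, 40)), np.full((5, 40), 30.0))
        res = vc.bootstrap_support(mat, B=5, seed=0)
        for clade in res.support:
            assert 1 < len(clade) < 5

    def test_sparse_coverage_aborts_with_diagnostic(self):
        rng = np.random.default_rng(3)
        vaf = rng.uniform(size=(3, 6))
        depth = np.full((3, 6), 2.0)
        depth[:, 0] = 30.0  # a single co-covered site: most resamples miss it
        mat = make_vaf_matrix(vaf, depth)
        ref = vc.ward_cluster(vc.pairwise_distance(mat, min_pair_depth=2))
        with pytest.raises(RuntimeError, match="dropped|no co-covered|replicates"):
            vc.bootstrap_support(mat, B=40, seed=0, reference=ref)


class TestCutAndScore:
    def test_truth_equal_to_partition_scores_one(self):
        rng = np.random.default_rng(4)
        col = np.repeat([0.0, 0.5, 1.0], 3)
        vaf = np.tile(col[:, None], (1, 50)) + rng.normal(0, 0.01, size=(9, 50))
        vaf = np.clip(vaf, 0, 1)
        mat = make_vaf_matrix(vaf, np.full((9, 50), 30.0))
        tree = vc.ward_cluster(vc.pairwise_distance(mat))
        truth = {f"s{i}": i // 3 for i in range(9)}
        _, ari = vc.cut_and_score(tree, 3, {k: str(v) for k, v in truth.items()})
        assert ari == pytest.approx(1.0)

    def test_single_cluster_scores_zero(self):
        rng = np.random.default_rng(5)
        mat = make_vaf_matrix(rng.uniform(size=(6, 40)), np.full((6, 40), 30.0))
        tree = vc.ward_cluster(vc.pairwise_distance(mat))
        _, ari = vc.cut_and_score(tree, 1, {f"s{i}": str(i % 2) for i in range(6)})
        assert ari == pytest.approx(0.0)

    def test_species_recovery_on_strong_cohort(self, strong_vaf_matrix):
        truth, mat = strong_vaf_matrix
        tree = vc.ward_cluster(vc.pairwise_distance(mat))
        pure = {s: l for s, l in truth.sample_labels.items() if "F1" not in l}
        _, ari = vc.cut_and_score(tree, 3, pure)
        assert ari == pytest.approx(1.0)
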