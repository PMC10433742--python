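import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import squareform

from mirsig import clustering
from mirsig.matrix import ExpressionMatrix
from mirsig.normalization import log2_and_center

from conftest import upgma_oracle_heights


def _matrix(values, groups=None):
    values = np.asarray(values, dtype=float)
    frame = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    return ExpressionMatrix(frame, groups)


class TestUncenteredPearson:
    def test_proportional_vectors_distance_zero(self):
        assert clustering.uncentered_pearson_distance([1, 2, 3], [2, 4, 6]) == pytest.approx(0.0)

    def test_orthogonal_distance_one(self):
        assert clustering.uncentered_pearson_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_computed_half(self):
        # s = (0+1+0)/sqrt(2*2) = 1/2
        assert clustering.uncentered_pearson_distance([1, 1, 0], [0, 1, 1]) == pytest.approx(0.5)

    def test_all_zero_vector_convention(self):
        assert clustering.uncentered_pearson_distance([0, 0, 0], [1, 2, 3]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            clustering.uncentered_pearson_distance([1, 2], [1, 2, 3])

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=8),
        st.floats(0.01, 50),
        st.floats(0.01, 50),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, xs, a, b, seed):
        x = np.array(xs)
        rng = np.random.default_rng(seed)
        y = rng.normal(size=len(x))
        d1 = clustering.uncentered_pearson_distance(x, y)
        d2 = clustering.uncentered_pearson_distance(a * x, b * y)
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_not_shift_invariant(self):
        # unlike centered Pearson: shifting changes the similarity
        s = 1 - clustering.uncentered_pearson_distance([1, 2], [2, 3])
        assert s != pytest.approx(1.0)


class TestAverageLinkage:
    def test_two_items_single_merge(self):
        m = _matrix([[1.0, 0.0], [0.0, 1.0]])
        tree = clustering.average_linkage(m, "genes")
        assert tree.Z.shape == (1, 4)
        assert tree.Z[0, 2] == pytest.approx(1.0)  # orthogonal

    def test_three_item_upgma_arithmetic(self):
        """d(1,2)=0.1, d(1,3)=d(2,3)=0.5 -> merge (1,2)@0.1 then @0.5."""
        D = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]])
        from scipy.cluster.hierarchy import linkage

        Z = linkage(squareform(D), method="average")
        tree = clustering.LinkageTree(Z, ["a", "b", "c"])
        assert tree.Z[0, 2] == pytest.approx(0.1)
        assert tree.Z[1, 2] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = _matrix(rng.normal(size=(20, 6)))
        tree = clustering.average_linkage(m, "genes")
        D = squareform(clustering.uncentered_distance_matrix(m.values.to_numpy()))
        oracle = upgma_oracle_heights(D)
        np.testing.assert_allclose(np.sort(tree.Z[:, 2]), np.sort(oracle), atol=1e-9)

    def test_heights_monotone(self, small_dataset):
        sub = small_dataset.matrix.values.iloc[:200]
        m = ExpressionMatrix(sub)
        tree = clustering.average_linkage(m, "genes")
        assert np.all(np.diff(tree.Z[:, 2]) >= -1e-12)

    def test_sample_axis(self, small_dataset):
        tree = clustering.average_linkage(small_dataset.matrix, "samples")
        assert tree.n_leaves == 18


class TestCutTree:
    @pytest.fixture()
    def toy_tree(self):
        """4 leaves: pairs (0,1)@0.1 and (2,3)@0.15, joined @1.0."""
        Z = np.array(
            [[0.0, 1.0, 0.1, 2.0], [2.0, 3.0, 0.15, 2.0], [4.0, 5.0, 1.0, 4.0]]
        )
        return clustering.LinkageTree(Z, ["a", "b", "c", "d"])

    def test_fraction_one_single_cluster(self, toy_tree):
        clusters = clustering.cut_tree(toy_tree, fraction=1.0, min_size=1)
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == ["a", "b", "c", "d"]

    def test_fraction_zero_all_singletons_dropped(self, toy_tree):
        assert clustering.cut_tree(toy_tree, fraction=0.0, min_size=2) == []

    def test_pairs_below_cut(self, toy_tree):
        clusters = clustering.cut_tree(toy_tree, fraction=0.2, min_size=2)
        assert [sorted(c.members) for c in clusters] == [["a", "b"], ["c", "d"]]
        assert [c.id for c in clusters] == [1, 2]

    def test_absolute_cut(self, toy_tree):
        clusters = clustering.cut_tree(toy_tree, absolute=0.12, min_size=2)
        assert [sorted(c.members) for c in clusters] == [["a", "b"]]

    def test_partition_covers_all_leaves(self, small_dataset):
        sub = ExpressionMatrix(small_dataset.matrix.values.iloc[:300])
        tree = clustering.average_linkage(sub, "genes")
        clusters = clustering.cut_tree(tree, fraction=0.3, min_size=1)
        members = [g for c in clusters for g in c.members]
        assert sorted(members) == sorted(sub.gene_ids)
        assert len(members) == len(set(members))  # disjoint


class TestCollectiveTest:
    def _grouped(self, values):
        n = np.asarray(values).shape[1]
        half = n // 2
        groups = pd.Series(
            ["A"] * half + ["B"] * (n - half),
            index=[f"s{j}" for j in range(n)],
        )
        return _matrix(values, groups)

    def test_identical_groups_p_one(self):
        m = self._grouped([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]] * 3)
        res = clustering.collective_test(m, ["g0", "g1"], "A", "B")
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_singleton_cluster_equals_gene_t_test(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        vals = rng.normal(size=(1, 10))
        m = self._grouped(vals)
        res = clustering.collective_test(m, ["g0"], "A", "B")
        t, p = stats.ttest_ind(vals[0, :5], vals[0, 5:])
        assert res.t == pytest.approx(float(t))
        assert res.p == pytest.approx(float(p))

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 0.2, size=(30, 12))
        vals[:, :6] += 1.0
        m = self._grouped(vals)
        res = clustering.collective_test(m, list(m.gene_ids), "A", "B")
        assert res.p < 0.01
        assert res.direction == "up"

    def test_zero_variance_equal_means(self):
        m = self._grouped([[1.0, 1.0, 1.0, 1.0]])
        res = clustering.collective_test(m, ["g0"], "A", "B")
        assert res.p == 1.0


class TestExtractDifferentialClusters:
    def test_planted_clusters_extracted_with_matching_directions(self, small_dataset):
        matrix = log2_and_center(small_dataset.matrix, log=False)
        tree = clustering.average_linkage(matrix, "genes")
        clusters = clustering.cut_tree(tree, fraction=0.2, min_size=10)
        contrasts = [("mimicA", "control"), ("mimicB", "control")]
        extracted = clustering.extract_differential_clusters(
            matrix, clusters, contrasts, alpha=0.05
        )
        assert len(extracted) == 5
        # planted per-group shifts for each truth cluster (mimicA, mimicB)
        planted = {1: (-1, 0), 2: (0, 1), 3: (-1, -1), 4: (1, 1), 5: (1, -1)}
        sign = {"up": 1, "down": -1}
        seen = set()
        for cluster in extracted:
            truth_ids = small_dataset.truth_clusters[cluster.members]
            dominant = int(truth_ids.mode()[0])
            seen.add(dominant)
            for contrast, shift in zip(contrasts, planted[dominant]):
                call = cluster.direction_pattern[contrast]
                if call != "unchanged":
                    # a significant collective call must never contradict the
                    # planted direction (the shared cofactor limits power, so
                    # an occasional "unchanged" on a true shift is expected)
                    assert shift != 0 and sign[call] == np.sign(shift)
        assert seen == {1, 2, 3, 4, 5}

    def test_alpha_zero_empty(self, small_dataset):
        matrix = log2_and_center(small_dataset.matrix, log=False)
        tree = clustering.average_linkage(matrix, "genes")
        clusters = clustering.cut_tree(tree, fraction=0.2, min_size=10)
        assert (
            clustering.extract_differential_clusters(
                matrix, clusters, [("mimicA", "control")], alpha=0.0
            )
            == []
        )
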