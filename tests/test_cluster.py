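import numpy as np
import pandas as pd
import pytest

from rtksubtyper.cluster import (
    consensus_cluster,
    cut_clusters,
    dendrogram_to_newick,
    hier_cluster,
    pearson_distance,
    silhouette_widths,
)
from tests.conftest import random_distance_matrix


# ---------------------------------------------------------------- oracles


def upgma_oracle(d: np.ndarray):
    """O(n^3) average-linkage clustering straight from the definition.

    Clusters are merged at the unweighted mean of the pairwise original
    distances; ties break toward the lowest-index pair.  Returns the merge
    heights and the partition after each merge.
    """
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    heights, partitions = [], []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
        heights.append(dist)
        partitions.append([sorted(c) for c in clusters])
    return heights, partitions


def silhouette_oracle(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Literal per-sample silhouette: a, b computed by explicit loops."""
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue  # singleton -> 0
        a = np.mean([d[i, j] for j in own])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == c])
            for c in set(labels)
            if c != labels[i]
        )
        out[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return out


def partition_sets(labels) -> set:
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return {tuple(sorted(g)) for g in groups.values()}


# ---------------------------------------------------------------- distance


class TestPearsonDistance:
    def test_identical_profiles_zero(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert pearson_distance(m).loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_two(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]})
        assert pearson_distance(m).loc["a", "b"] == pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_half_correlation(self):
        # r((1,2,3),(1,3,2)) = 0.5 -> d = 0.5
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 3.0, 2.0]})
        assert pearson_distance(m).loc["a", "b"] == pytest.approx(0.5, abs=1e-12)

    def test_constant_profile_named_in_error(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flatling": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flatling"):
            pearson_distance(m)

    def test_matrix_properties(self, planted):
        d = pearson_distance(planted.matrix).to_numpy()
        assert np.allclose(d, d.T, atol=1e-12)
        assert np.allclose(np.diag(d), 0.0)
        assert d.min() >= 0 and d.max() <= 2


# ---------------------------------------------------------------- UPGMA


class TestHierCluster:
    def test_well_separated_pairs_merge_first(self):
        ids = list("abcd")
        d = np.full((4, 4), 1.9)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.01
        d[2, 3] = d[3, 2] = 0.01
        z = hier_cluster(pd.DataFrame(d, index=ids, columns=ids))
        first_two = {frozenset(map(int, row[:2])) for row in z[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_three_point_hand_example(self):
        # d(1,2)=0.1, d(1,3)=d(2,3)=1.0 -> merge (1,2)@0.1 then @1.0
        ids = list("abc")
        d = np.array([[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]])
        z = hier_cluster(pd.DataFrame(d, index=ids, columns=ids))
        assert z[0, :2].tolist() == [0, 1]
        assert z[0, 2] == pytest.approx(0.1)
        assert z[1, 2] == pytest.approx(1.0)
        assert partition_sets(cut_clusters(z, 2)) == {(0, 1), (2,)}

    def test_cut_extremes(self):
        rng = np.random.default_rng(1)
        d = random_distance_matrix(rng, 6)
        z = hier_cluster(d)
        assert len(set(cut_clusters(z, 1))) == 1
        assert len(set(cut_clusters(z, 6))) == 6
        with pytest.raises(ValueError, match="out of range"):
            cut_clusters(z, 7)

    def test_matches_brute_force_oracle(self):
        # random continuous distances (no ties): merge heights and every
        # k-partition must agree with the definitional O(n^3) algorithm
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n = int(rng.integers(3, 9))
            d = random_distance_matrix(rng, n)
            z = hier_cluster(d)
            heights, partitions = upgma_oracle(d.to_numpy())
            assert np.allclose(sorted(z[:, 2]), sorted(heights), atol=1e-9)
            for k in range(1, n + 1):
                labels = cut_clusters(z, k)
                if k == n:
                    expected = {(i,) for i in range(n)}
                else:
                    expected = {tuple(c) for c in partitions[n - k - 1]}
                assert partition_sets(labels) == expected

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(3)
        d = random_distance_matrix(rng, 5)
        nwk = dendrogram_to_newick(hier_cluster(d), d.index)
        assert nwk.endswith(";")
        for leaf in d.index:
            assert leaf in nwk


# ---------------------------------------------------------------- consensus


class TestConsensus:
    def test_planted_blocks_are_stable(self, planted):
        markers = [
            g for s in ("S1", "S2", "S3") for g in planted.true_marker_sets[s]
        ] + planted.rtk_genes
        res = consensus_cluster(planted.matrix.loc[markers], k=3, iterations=250, seed=5)
        c = res.consensus.to_numpy()
        truth = planted.true_subtype.to_numpy()
        same = truth[:, None] == truth[None, :]
        off_diag = ~np.eye(len(truth), dtype=bool)
        assert c[same & off_diag].mean() >= 0.9
        assert c[~same].mean() <= 0.1

    def test_same_seed_identical(self, planted):
        sub = planted.matrix.iloc[:50]
        a = consensus_cluster(sub, k=2, iterations=40, seed=9)
        b = consensus_cluster(sub, k=2, iterations=40, seed=9)
        pd.testing.assert_frame_equal(a.consensus, b.consensus)

    def test_full_feature_fraction_is_binary(self, planted):
        res = consensus_cluster(
            planted.matrix.iloc[:40], k=2, iterations=25, feature_fraction=1.0, seed=0
        )
        values = np.unique(res.consensus.to_numpy())
        assert set(values) <= {0.0, 1.0}

    def test_matrix_invariants_asserted(self, planted):
        res = consensus_cluster(planted.matrix.iloc[:30], k=2, iterations=20, seed=1)
        res.validate()
        c = res.consensus.to_numpy()
        assert np.allclose(np.diag(c), 1.0)

    @pytest.mark.parametrize(
        "kwargs", [{"feature_fraction": 0.0}, {"feature_fraction": 1.5}, {"iterations": 0}]
    )
    def test_invalid_parameters(self, planted, kwargs):
        with pytest.raises(ValueError):
            consensus_cluster(planted.matrix.iloc[:30], k=2, **kwargs)


# ---------------------------------------------------------------- silhouette


class TestSilhouette:
    def test_duplicated_points_score_one(self):
        ids = list("abcd")
        d = np.array(
            [
                [0.0, 0.0, 1.5, 1.5],
                [0.0, 0.0, 1.5, 1.5],
                [1.5, 1.5, 0.0, 0.0],
                [1.5, 1.5, 0.0, 0.0],
            ]
        )
        res = silhouette_widths(
            pd.DataFrame(d, index=ids, columns=ids), [1, 1, 2, 2]
        )
        assert np.allclose(res.widths, 1.0)

    def test_singleton_cluster_scores_zero(self):
        rng = np.random.default_rng(4)
        d = random_distance_matrix(rng, 5)
        res = silhouette_widths(d, [1, 1, 1, 1, 2])
        assert res.widths.iloc[4] == 0.0

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            n = int(rng.integers(4, 11))
            d = random_distance_matrix(rng, n)
            labels = rng.integers(1, int(rng.integers(2, 4)) + 1, n)
            if len(set(labels)) < 2:
                continue
            mine = silhouette_widths(d, labels).widths.to_numpy()
            assert np.max(np.abs(mine - silhouette_oracle(d.to_numpy(), labels))) <= 1e-12

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(8)
        d = random_distance_matrix(rng, 12)
        labels = np.array([1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3, 3])
        mine = silhouette_widths(d, labels).widths.to_numpy()
        ref = silhouette_samples(d.to_numpy(), labels, metric="precomputed")
        assert np.allclose(mine, ref, atol=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        d = random_distance_matrix(rng, 10)
        labels = np.array([1, 1, 2, 2, 2, 3, 3, 3, 3, 1])
        swapped = np.select([labels == 1, labels == 2, labels == 3], [3, 1, 2])
        a = silhouette_widths(d, labels).widths
        b = silhouette_widths(d, swapped).widths
        assert np.allclose(a, b)

    def test_single_cluster_rejected(self):
        rng = np.random.default_rng(10)
        d = random_distance_matrix(rng, 4)
        with pytest.raises(ValueError, match="2 clusters"):
            silhouette_widths(d, [1, 1, 1, 1])

    def test_undetermined_flagging(self):
        # a sample sitting inside the other cluster must get a negative width
        ids = list("abcde")
        pts = np.array([0.0, 0.1, 5.0, 5.1, 4.9])
        d = np.abs(pts[:, None] - pts[None, :])
        res = silhouette_widths(
            pd.DataFrame(d, index=ids, columns=ids), [1, 1, 2, 2, 1]
        )
        assert "e" in res.undetermined
        assert set(res.undetermined) == {"e"}
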