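"""Resampling, K-means partitioning, consensus accumulation and assignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import hrsclust as hc
from hrsclust.consensus_core import RunRecord


def brute_force_consensus(runs, n):
    """Pair-counting oracle: explicit loops over runs and item pairs."""
    together = np.zeros((n, n))
    both = np.zeros((n, n))
    for run in runs:
        idx = list(run.item_indices)
        lab = {i: l for i, l in zip(idx, run.labels)}
        for a in idx:
            for b in idx:
                both[a, b] += 1
                if lab[a] == lab[b]:
                    together[a, b] += 1
    with np.errstate(invalid="ignore"):
        m = np.where(both > 0, together / np.maximum(both, 1), 0.0)
    np.fill_diagonal(m, 1.0)
    return m, both


class TestSubsampleItems:
    @pytest.mark.parametrize(
        "n,fraction,expected",
        [(5564, 0.8, 4451), (10, 0.8, 8), (7, 1.0, 7)],
    )
    def test_sample_size_is_floor(self, n, fraction, expected):
        idx = hc.subsample_items(n, fraction, np.random.default_rng(0))
        assert len(idx) == expected
        assert len(np.unique(idx)) == len(idx)
        assert idx.min() >= 0 and idx.max() < n

    def test_full_fraction_returns_everything(self):
        idx = hc.subsample_items(10, 1.0, np.random.default_rng(0))
        np.testing.assert_array_equal(idx, np.arange(10))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            hc.subsample_items(10, 0.0, np.random.default_rng(0))


class TestKMeansPartition:
    def test_separated_pairs_are_colabeled(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
        labels = hc.kmeans_partition(X, 2, np.random.default_rng(0))
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        assert set(labels) == {1, 2}

    def test_k_one_is_single_cluster(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        labels = hc.kmeans_partition(X, 1, np.random.default_rng(0))
        assert set(labels) == {1}

    def test_k_equals_n_has_zero_wcss(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        labels = hc.kmeans_partition(X, 6, np.random.default_rng(0))
        assert len(set(labels)) == 6  # every point its own centroid

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            hc.kmeans_partition(np.zeros((2, 2)), 3, np.random.default_rng(0))


class TestAccumulateConsensus:
    def test_hand_counted_example(self):
        runs = [
            RunRecord(k=2, iteration=0, item_indices=np.array([0, 1, 2]),
                      labels=np.array([1, 1, 2])),
            RunRecord(k=2, iteration=1, item_indices=np.array([0, 1]),
                      labels=np.array([1, 2])),
        ]
        cm = hc.accumulate_consensus(runs, n=3)
        assert cm.matrix[0, 1] == pytest.approx(0.5)  # together 1 of 2 runs
        assert cm.matrix[0, 2] == 0.0  # co-sampled once, apart
        assert cm.matrix[1, 2] == 0.0
        assert cm.cosample_counts[0, 1] == 2
        assert cm.cosample_counts[0, 2] == 1

    def test_identical_full_sample_partitions_are_binary(self):
        labels = np.array([1, 1, 2, 2, 1])
        runs = [
            RunRecord(k=2, iteration=i, item_indices=np.arange(5), labels=labels)
            for i in range(7)
        ]
        cm = hc.accumulate_consensus(runs, n=5)
        off = cm.offdiagonal_values()
        assert set(off.tolist()) <= {0.0, 1.0}

    def test_zero_runs_rejected(self):
        with pytest.raises(ValueError):
            hc.accumulate_consensus([], n=5)

    def test_inconsistent_k_rejected(self):
        runs = [
            RunRecord(k=2, iteration=0, item_indices=np.arange(3),
                      labels=np.array([1, 1, 2])),
            RunRecord(k=3, iteration=1, item_indices=np.arange(3),
                      labels=np.array([1, 2, 3])),
        ]
        with pytest.raises(ValueError, match="same k"):
            hc.accumulate_consensus(runs, n=3)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        k = int(rng.integers(2, 5))
        runs = []
        for it in range(int(rng.integers(3, 15))):
            m = int(rng.integers(k, n + 1))
            idx = np.sort(rng.choice(n, size=m, replace=False))
            labels = rng.integers(1, k + 1, size=m)
            runs.append(RunRecord(k=k, iteration=it, item_indices=idx, labels=labels))
        cm = hc.accumulate_consensus(runs, n)
        oracle_m, oracle_counts = brute_force_consensus(runs, n)
        np.testing.assert_array_equal(np.asarray(cm.matrix, dtype=float), oracle_m)
        np.testing.assert_array_equal(cm.cosample_counts, oracle_counts)


class TestRunConsensus:
    def test_covers_k_range_with_exact_iteration_count(self, highsep_cohort):
        features = hc.zscore_continuous(hc.encode_features(highsep_cohort))
        config = hc.ConsensusConfig(k_min=2, k_max=10, iterations=4, seed=0)
        matrices, runs = hc.run_consensus(features, config, return_runs=True)
        assert sorted(matrices) == list(range(2, 11))
        assert all(len(runs[k]) == 4 for k in matrices)

    def test_deterministic_given_seed(self, highsep_cohort):
        features = hc.zscore_continuous(hc.encode_features(highsep_cohort))
        config = hc.ConsensusConfig(k_min=3, k_max=3, iterations=6, seed=42)
        first = hc.run_consensus(features, config)[3]
        second = hc.run_consensus(features, config)[3]
        np.testing.assert_array_equal(first.matrix, second.matrix)

    def test_too_small_n_rejected(self):
        with pytest.raises(ValueError, match="k_max"):
            hc.run_consensus(np.zeros((5, 3)), hc.ConsensusConfig(k_max=10))

    def test_matrix_invariants(self, highsep_consensus):
        for cm in highsep_consensus.values():
            m = np.asarray(cm.matrix, dtype=float)
            np.testing.assert_array_equal(m, m.T)
            np.testing.assert_array_equal(np.diag(m), 1.0)
            assert m.min() >= 0.0 and m.max() <= 1.0

    def test_separable_fixture_is_near_binary_at_true_k(self, highsep_consensus):
        off = highsep_consensus[4].offdiagonal_values()
        decisive = (off <= 0.02) | (off >= 0.98)
        assert decisive.mean() >= 0.99


class TestAssignFinalClusters:
    def test_perfect_two_block_matrix(self, consensus_from_values):
        # items 0,1 together; 2,3 together; blocks apart
        cm = consensus_from_values([1, 0, 0, 0, 0, 1], n=4)
        labels = hc.assign_final_clusters(cm)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_all_ones_matrix_is_deterministic_and_flagged(
        self, consensus_from_values, caplog
    ):
        cm = consensus_from_values([1.0] * 6, n=4)
        with caplog.at_level("WARNING", logger="hrsclust.consensus_core"):
            first = hc.assign_final_clusters(cm)
        cm2 = consensus_from_values([1.0] * 6, n=4)
        second = hc.assign_final_clusters(cm2)
        np.testing.assert_array_equal(first, second)
        assert any("degenerate" in rec.message for rec in caplog.records)

    def test_labels_renumbered_by_descending_size(self, consensus_from_values):
        # one block of 3 (items 0,1,2), one of 2 (3,4), upper triangle by rows
        cm = consensus_from_values([1, 1, 0, 0, 1, 0, 0, 0, 0, 1], n=5)
        cm.k = 2
        labels = hc.assign_final_clusters(cm)
        assert list(labels) == [1, 1, 1, 2, 2]

    def test_planted_structure_recovery(self, highsep_cohort, highsep_consensus):
        labels = hc.assign_final_clusters(highsep_consensus[4])
        ari = adjusted_rand_score(highsep_cohort.true_labels, labels)
        assert ari > 0.9

    def test_permutation_consistency(self, highsep_consensus):
        cm = highsep_consensus[4]
        labels = hc.assign_final_clusters(cm)
        rng = np.random.default_rng(1)
        perm = rng.permutation(cm.n_items)
        permuted = hc.ConsensusMatrix(
            k=cm.k,
            matrix=cm.matrix[np.ix_(perm, perm)],
            cosample_counts=cm.cosample_counts[np.ix_(perm, perm)],
        )
        labels_perm = hc.assign_final_clusters(permuted)
        assert adjusted_rand_score(labels_perm, labels[perm]) == pytest.approx(1.0)
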