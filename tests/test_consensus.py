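"""Consensus clustering: connectivity matrices, Eq.-style averaging, K choice."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from klic.consensus import (
    ConsensusMatrix,
    DatasetMatrix,
    Partition,
    ResamplingScheme,
    ambiguity_proportion,
    cluster_data,
    coclustering_matrix,
    consensus_cluster,
    consensus_matrix,
    make_clusterer,
    pam_labels,
    select_k_monti,
    subsample,
)
from klic.evalio import adjusted_rand_index
from klic.simdata import SimulationConfig, generate_dataset

from conftest import random_partition_labels


class TestCoclustering:
    @pytest.mark.parametrize(
        "labels,mask,expected",
        [
            ([1, 1, 2], None, [[1, 1, 0], [1, 1, 0], [0, 0, 1]]),
            ([1, 1, 1], None, [[1, 1, 1], [1, 1, 1], [1, 1, 1]]),
            ([1, 1, 2], [True, True, False], [[1, 1, 0], [1, 1, 0], [0, 0, 0]]),
        ],
    )
    def test_hand_examples(self, labels, mask, expected):
        part = Partition(labels, K=2, included_mask=mask)
        assert coclustering_matrix(part, 3).values.tolist() == expected

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_label_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 12, 4
        labels = random_partition_labels(rng, n, k)
        mask = rng.random(n) < 0.8
        mask[:2] = True
        base = coclustering_matrix(Partition(labels, K=k, included_mask=mask), n)
        perm = rng.permutation(k) + 1
        relabeled = coclustering_matrix(
            Partition(perm[labels - 1], K=k, included_mask=mask), n)
        np.testing.assert_array_equal(base.values, relabeled.values)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="items"):
            coclustering_matrix(Partition([1, 2], K=2), 3)


class TestSubsample:
    def test_full_item_proportion_keeps_everything(self):
        scheme = ResamplingScheme(n_runs=3, item_proportion=1.0, seed=0)
        for run in range(3):
            items, feats = subsample(scheme, 10, 4, run)
            assert items.tolist() == list(range(10))
            assert feats.tolist() == list(range(4))

    def test_sample_sizes_are_ceilings(self):
        scheme = ResamplingScheme(n_runs=1, item_proportion=0.8,
                                  feature_proportion=0.5, seed=1)
        items, feats = subsample(scheme, 10, 5, 0)
        assert len(set(items.tolist())) == 8
        assert len(set(feats.tolist())) == 3

    def test_deterministic_given_seed_and_run(self):
        scheme = ResamplingScheme(n_runs=5, item_proportion=0.6, seed=7)
        a = subsample(scheme, 20, 6, 3)
        b = subsample(scheme, 20, 6, 3)
        assert a[0].tolist() == b[0].tolist() and a[1].tolist() == b[1].tolist()
        c = subsample(scheme, 20, 6, 4)
        assert a[0].tolist() != c[0].tolist() or a[1].tolist() != c[1].tolist()

    def test_too_small_sample_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            subsample(ResamplingScheme(n_runs=1, item_proportion=0.1, seed=0), 5, 2, 0)


class TestConsensusMatrix:
    def test_two_run_hand_fixture(self):
        run1 = coclustering_matrix(Partition([1, 1, 2], K=2), 3)
        mask = np.array([True, False, True])
        run2 = coclustering_matrix(Partition([1, 2, 1], K=2, included_mask=mask), 3)
        delta = consensus_matrix([run1, run2])
        np.testing.assert_allclose(
            delta.values, [[1, 1, 0.5], [1, 1, 0], [0.5, 0, 1]])
        assert delta.copair_counts[0, 2] == 2 and delta.copair_counts[0, 1] == 1

    def test_identical_full_runs_reproduce_connectivity(self, rng):
        labels = random_partition_labels(rng, 8, 3)
        run = coclustering_matrix(Partition(labels, K=3), 8)
        delta = consensus_matrix([run] * 5)
        np.testing.assert_array_equal(delta.values, run.values)

    def test_never_cosampled_pair_is_zero(self):
        m1 = np.array([True, True, False])
        m2 = np.array([True, False, True])
        runs = [coclustering_matrix(Partition([1, 1, 1], K=1, included_mask=m),
                                    3) for m in (m1, m2)]
        delta = consensus_matrix(runs)
        assert delta.values[1, 2] == 0.0
        assert delta.copair_counts[1, 2] == 0

    def test_symmetric_unit_interval_unit_diagonal(self, rng):
        for _ in range(20):
            runs = []
            for _ in range(5):
                mask = rng.random(10) < 0.7
                mask[:2] = True
                labels = random_partition_labels(rng, 10, 3)
                runs.append(coclustering_matrix(
                    Partition(labels, K=3, included_mask=mask), 10))
            delta = consensus_matrix(runs)
            np.testing.assert_array_equal(delta.values, delta.values.T)
            assert delta.values.min() >= 0.0 and delta.values.max() <= 1.0
            sampled = np.diag(delta.copair_counts) > 0
            np.testing.assert_array_equal(np.diag(delta.values)[sampled], 1.0)

    def test_adding_identical_run_moves_entries_toward_it(self, rng):
        runs = []
        for _ in range(4):
            labels = random_partition_labels(rng, 8, 3)
            runs.append(coclustering_matrix(Partition(labels, K=3), 8))
        extra = runs[0]
        before = consensus_matrix(runs).values
        after = consensus_matrix(runs + [extra]).values
        toward_one = extra.values == 1
        assert (after[toward_one] >= before[toward_one] - 1e-12).all()
        assert (after[~toward_one] <= before[~toward_one] + 1e-12).all()

    def test_feature_only_resampling_is_mean_and_psd(self):
        data, _ = generate_dataset(SimulationConfig(
            n_clusters=3, n_per_cluster=8, separability=1.0, n_relevant=4, seed=3))
        scheme = ResamplingScheme(n_runs=20, item_proportion=1.0,
                                  feature_proportion=0.5, seed=5)
        delta = consensus_cluster(data, 3, scheme)
        assert (delta.copair_counts == 20).all()
        min_eig = np.linalg.eigvalsh(delta.values)[0]
        assert min_eig >= -1e-8

    def test_inconsistent_shapes_raise(self):
        a = coclustering_matrix(Partition([1, 1], K=1), 2)
        b = coclustering_matrix(Partition([1, 1, 1], K=1), 3)
        with pytest.raises(ValueError, match="shape"):
            consensus_matrix([a, b])


class TestConsensusCluster:
    def test_well_separated_near_binary_vs_noise_ambiguous(self):
        scheme = ResamplingScheme(n_runs=30, seed=2)
        clean, _ = generate_dataset(SimulationConfig(
            n_clusters=6, n_per_cluster=10, separability=5.0, seed=1))
        noisy, _ = generate_dataset(SimulationConfig(
            n_clusters=6, n_per_cluster=10, separability=0.0, seed=1))
        assert ambiguity_proportion(consensus_cluster(clean, 6, scheme)) < 0.05
        assert ambiguity_proportion(consensus_cluster(noisy, 6, scheme)) > 0.2

    def test_no_item_resampling_deterministic_clusterer_binary(self):
        data, _ = generate_dataset(SimulationConfig(
            n_clusters=2, n_per_cluster=6, separability=4.0, seed=0))
        scheme = ResamplingScheme(n_runs=10, item_proportion=1.0, seed=0)
        delta = consensus_cluster(data, 2, scheme,
                                  clusterer=make_clusterer("hier-average"))
        assert np.isin(delta.values, (0.0, 1.0)).all()

    def test_clusterer_failure_reported_with_run_context(self):
        data, _ = generate_dataset(SimulationConfig(
            n_clusters=2, n_per_cluster=4, seed=0))

        def broken(x, k, rng):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="run 0"):
            consensus_cluster(data, 2, ResamplingScheme(n_runs=2, seed=0),
                              clusterer=broken)


class TestSelectKMonti:
    def test_binary_beats_ambiguous(self):
        binary = ConsensusMatrix(np.eye(4), n_runs=10, K=2)
        fuzzy = ConsensusMatrix(np.full((4, 4), 0.5) + 0.5 * np.eye(4),
                                n_runs=10, K=3)
        assert select_k_monti({2: binary, 3: fuzzy}) == 2

    def test_tie_goes_to_smallest_k(self):
        binary = {k: ConsensusMatrix(np.eye(4), n_runs=10, K=k) for k in (3, 2, 5)}
        assert select_k_monti(binary) == 2

    def test_empty_map_raises(self):
        with pytest.raises(ValueError):
            select_k_monti({})


class TestClusterData:
    def test_two_points_two_clusters(self):
        data = DatasetMatrix([[0.0], [10.0]], ("a", "b"), ("x",))
        part = cluster_data(data, 2)
        assert sorted(part.labels.tolist()) == [1, 2]

    def test_kmeans_recovers_separated_clusters(self):
        hits = 0
        for seed in range(5):
            data, truth = generate_dataset(SimulationConfig(
                n_clusters=6, n_per_cluster=20, separability=5.0, seed=seed))
            part = cluster_data(data, 6, seed=seed)
            hits += adjusted_rand_index(part, truth) == 1.0
        assert hits >= 4

    def test_pam_correlation_toy_recovers_blocks(self):
        # two profile shapes; correlation distance separates them exactly
        x = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0],
                      [3.0, 2.0, 1.0], [6.0, 4.0, 2.0]])
        data = DatasetMatrix(x, ("a", "b", "c", "d"), ("t1", "t2", "t3"))
        part = cluster_data(data, 2, method="pam", metric="correlation")
        assert part.labels[0] == part.labels[1]
        assert part.labels[2] == part.labels[3]
        assert part.labels[0] != part.labels[2]

    def test_pam_matches_bruteforce_medoids(self, rng):
        from itertools import combinations
        relative_gaps = []
        for _ in range(5):
            pts = rng.standard_normal((7, 2))
            dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            labels = pam_labels(dist, 2)
            optimum = min(dist[:, list(meds)].min(axis=1).sum()
                          for meds in combinations(range(7), 2))
            gap = _pam_cost(dist, labels) - optimum
            assert gap >= -1e-9  # never beats the exhaustive optimum
            relative_gaps.append(gap / optimum)
        # the swap search is local: allow at most one near-miss within 10%
        assert sum(g <= 1e-12 for g in relative_gaps) >= 4
        assert max(relative_gaps) <= 0.10

    def test_k_larger_than_n_raises(self):
        data = DatasetMatrix([[0.0], [1.0]], ("a", "b"), ("x",))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_data(data, 3)


def _pam_cost(dist: np.ndarray, labels: np.ndarray) -> float:
    """Cost of the best medoid per cluster for the given assignment."""
    total = 0.0
    for k in np.unique(labels):
        members = np.flatnonzero(labels == k)
        total += dist[np.ix_(members, members)].sum(axis=0).min()
    return float(total)
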