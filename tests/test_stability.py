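"""Jaccard/semantic stability statistics, stable-K selection, hierarchy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from sklearn.datasets import make_blobs
from sklearn.metrics import adjusted_rand_score

import ehrstates as e
from ehrstates.stability import cross_k_distance

from conftest import jaccard_brute, semantic_brute, true_snapshot_states


class TestJaccardStability:
    def test_identical_partitions_give_one(self):
        labels = np.array([0, 0, 1, 1, 2, 2, 2])
        assert e.jaccard_stability(labels, labels) == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        ref = np.array([0, 0, 1, 1, 2, 2])
        perm = np.array([2, 2, 0, 0, 1, 1])
        assert e.jaccard_stability(ref, perm) == pytest.approx(1.0)
        rng = np.random.default_rng(4)
        boot = rng.integers(0, 3, size=6)
        remap = np.array([1, 2, 0])
        assert e.jaccard_stability(ref, boot) == pytest.approx(
            e.jaccard_stability(remap[ref], boot)
        )

    def test_hand_enumerated_example(self):
        # ref {a,b},{c,d}; boot {a,b,c},{d}:
        #   n11=2, J11=2/3; n21=1, J21=1/4; n22=1, J22=|{d}|/|{c,d}|=1/2
        # J = (2*2/3 + 1*1/4 + 1*1/2)/4 = 25/48
        ref = np.array([0, 0, 1, 1])
        boot = np.array([0, 0, 0, 1])
        assert e.jaccard_stability(ref, boot) == pytest.approx(25 / 48)

    @settings(max_examples=50, deadline=None)
    @given(hst.integers(0, 2**31 - 1), hst.integers(2, 50))
    def test_matches_brute_force_on_random_partitions(self, seed, n):
        rng = np.random.default_rng(seed)
        ref = rng.integers(0, rng.integers(1, 6), size=n)
        boot = rng.integers(0, rng.integers(1, 6), size=n)
        j = e.jaccard_stability(ref, boot)
        assert 0.0 <= j <= 1.0
        assert j == pytest.approx(jaccard_brute(ref, boot), abs=1e-12)

    def test_disjoint_point_sets_error(self):
        with pytest.raises(ValueError):
            e.jaccard_stability(np.array([0, 1]), np.array([0, 1, 2]))


class TestSemanticStability:
    def test_identical_partitions_and_vocabularies(self):
        labels = np.array([0, 0, 1, 1])
        vocabs = {0: {1, 2}, 1: {3}}
        assert e.semantic_stability(vocabs, vocabs, labels, labels) == pytest.approx(1.0)

    def test_disjoint_vocabularies_give_zero(self):
        labels = np.array([0, 0, 1, 1])
        ref = {0: {1}, 1: {2}}
        boot = {0: {7}, 1: {8}}
        assert e.semantic_stability(ref, boot, labels, labels) == 0.0

    def test_empty_boot_vocabulary_contributes_zero(self):
        labels = np.array([0, 0, 1, 1])
        ref = {0: {1}, 1: {2}}
        boot = {0: {1}, 1: set()}
        assert e.semantic_stability(ref, boot, labels, labels) == pytest.approx(0.5)

    def test_missing_vocabularies_error(self):
        with pytest.raises(ValueError):
            e.semantic_stability(None, {}, np.array([0]), np.array([0]))

    @settings(max_examples=30, deadline=None)
    @given(hst.integers(0, 2**31 - 1))
    def test_three_cluster_toy_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        ref_l = rng.integers(0, 3, size=n)
        boot_l = rng.integers(0, 3, size=n)
        ref_v = {c: set(rng.choice(20, size=5, replace=False).tolist()) for c in range(3)}
        boot_v = {c: set(rng.choice(20, size=rng.integers(0, 6), replace=False).tolist())
                  for c in range(3)}
        s = e.semantic_stability(ref_v, boot_v, ref_l, boot_l)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(semantic_brute(ref_v, boot_v, ref_l, boot_l), abs=1e-12)


class TestKmeansSweep:
    def test_separable_blobs_recovered(self):
        X, y = make_blobs(n_samples=100, centers=2, cluster_std=0.2, random_state=0)
        runs = e.run_kmeans_sweep(X, [2], seed=0)
        assert adjusted_rand_score(y, runs[2].labels) == 1.0

    def test_k_below_two_rejected(self):
        X, _ = make_blobs(n_samples=30, centers=2, random_state=0)
        with pytest.raises(ValueError):
            e.run_kmeans_sweep(X, [1, 2], seed=0)

    def test_k_at_least_n_rejected(self):
        X, _ = make_blobs(n_samples=10, centers=2, random_state=0)
        with pytest.raises(ValueError):
            e.run_kmeans_sweep(X, [10], seed=0)

    def test_deterministic_given_seed(self):
        X, _ = make_blobs(n_samples=60, centers=3, random_state=1)
        a = e.run_kmeans_sweep(X, [3, 4], seed=5)
        b = e.run_kmeans_sweep(X, [3, 4], seed=5)
        for k in (3, 4):
            np.testing.assert_array_equal(a[k].labels, b[k].labels)

    def test_planted_states_recovered(self, hier_cohort, hier_matrix):
        truth = true_snapshot_states(hier_cohort, hier_matrix)
        runs = e.run_kmeans_sweep(hier_matrix, [4], seed=0)
        assert adjusted_rand_score(truth, runs[4].labels) >= 0.9


class TestBootstrap:
    def test_full_fraction_fixed_seed_perfect_stability(self):
        X, _ = make_blobs(n_samples=80, centers=3, cluster_std=0.2, random_state=0)
        prof = e.bootstrap_stability(
            X, [3], fd_schedule=[1.0], n_reps=5, seed=0, compute_semantic=False
        )
        assert (prof.values["J"] == 1.0).all()

    def test_subsample_smaller_than_k_skipped(self):
        X, _ = make_blobs(n_samples=30, centers=3, random_state=0)
        prof = e.bootstrap_stability(
            X, [8], fd_schedule=[0.5, 0.1], n_reps=2, seed=0, compute_semantic=False
        )
        assert set(np.round(prof.values["f_d"], 3)) == {0.5}

    def test_replicate_count_and_bounds(self):
        X, _ = make_blobs(n_samples=60, centers=3, random_state=0)
        prof = e.bootstrap_stability(
            X, [2, 3], fd_schedule=[0.5], n_reps=7, seed=1, compute_semantic=True
        )
        g = prof.values.groupby(["K", "f_d"]).size()
        assert (g == 7).all()
        assert prof.values["J"].between(0, 1).all()
        assert prof.values["S"].dropna().between(0, 1).all()

    def test_reproducible_given_seed(self):
        X, _ = make_blobs(n_samples=60, centers=3, random_state=0)
        a = e.bootstrap_stability(X, [3], fd_schedule=[0.5], n_reps=4, seed=2,
                                  compute_semantic=False)
        b = e.bootstrap_stability(X, [3], fd_schedule=[0.5], n_reps=4, seed=2,
                                  compute_semantic=False)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestSelectStableK:
    @staticmethod
    def profile_from_means(means: dict[int, float], f_d=0.5):
        rows = [(k, f_d, 0, v, np.nan) for k, v in means.items()]
        df = pd.DataFrame(rows, columns=["K", "f_d", "replicate", "J", "S"])
        return e.StabilityProfile(df, 1, (f_d,), tuple(means))

    def test_interior_local_maxima(self):
        prof = self.profile_from_means({2: 0.6, 3: 0.8, 4: 0.7, 5: 0.9, 6: 0.85})
        assert e.select_stable_k(prof) == [3, 5]

    def test_monotone_decreasing_keeps_left_endpoint(self):
        prof = self.profile_from_means({2: 0.9, 3: 0.8, 4: 0.7})
        assert e.select_stable_k(prof) == [2]

    def test_missing_fd_raises(self):
        prof = self.profile_from_means({2: 0.9, 3: 0.8}, f_d=0.25)
        with pytest.raises(ValueError):
            e.select_stable_k(prof)

    def test_planted_two_level_hierarchy_detected(self, hier_matrix):
        runs = e.run_kmeans_sweep(hier_matrix, range(2, 7), seed=0)
        prof = e.bootstrap_stability(
            hier_matrix, range(2, 7), fd_schedule=[0.5], n_reps=30, seed=0,
            ref_runs=runs, compute_semantic=False,
        )
        stable = e.select_stable_k(prof)
        assert {2, 4}.issubset(set(stable))


class TestHierarchy:
    @staticmethod
    def runs_from_labels(labels_by_k):
        return {
            k: e.ClusteringRun(K=k, labels=np.asarray(v), centroids=np.empty((k, 1)),
                               seed=0, inertia=0.0)
            for k, v in labels_by_k.items()
        }

    def test_perfectly_nested_partitions(self):
        # {a,b,c,d} -> {a,b},{c,d} -> singletons
        runs = self.runs_from_labels({
            2: np.repeat([0, 1], [8, 8]),
            4: np.repeat([0, 1, 2, 3], 4),
        })
        tree = e.build_hierarchy(runs, [2, 4])
        first_a, first_b = tree.merge_order()[0]
        assert first_a | first_b in ({0, 1}, {2, 3})
        assert tree.split_k[len(tree.linkage) - 1] == 2  # top split appears at K=2

    def test_single_stable_k_undefined(self):
        runs = self.runs_from_labels({2: np.repeat([0, 1], 4)})
        with pytest.raises(ValueError, match="hierarchy undefined"):
            e.build_hierarchy(runs, [2])

    def test_average_over_one_coarser_k_equals_its_matrix(self):
        fine = np.repeat([0, 1, 2], 5)
        coarse = np.repeat([0, 0, 1], 5)
        runs = self.runs_from_labels({2: coarse, 3: fine})
        tree = e.build_hierarchy(runs, [2, 3])
        np.testing.assert_allclose(
            tree.distance_matrix, cross_k_distance(fine, coarse)
        )

    def test_planted_siblings_merge_first(self, hier_matrix):
        runs = e.run_kmeans_sweep(hier_matrix, [2, 4], seed=0)
        tree = e.build_hierarchy(runs, [2, 4])
        # match fine clusters to parent groups via the K=2 partition
        from ehrstates.stability import _contingency

        n = _contingency(runs[4].labels, runs[2].labels)
        parent_of = n.argmax(axis=1)
        for sa, sb in tree.merge_order()[:2]:
            members = sa | sb
            parents = {parent_of[i] for i in members}
            assert len(parents) == 1, "siblings should merge before cross-parent"

    def test_newick_export_has_all_leaves(self):
        runs = self.runs_from_labels({
            2: np.repeat([0, 1], [8, 8]),
            4: np.repeat([0, 1, 2, 3], 4),
        })
        tree = e.build_hierarchy(runs, [2, 4])
        nwk = tree.to_newick()
        for i in range(4):
            assert f"state_{i}" in nwk


def test_stability_decay_with_less_data(hier_matrix):
    """Mean J at the true K degrades (in trend) as the subsample shrinks."""
    prof = e.bootstrap_stability(
        hier_matrix, [4], fd_schedule=[0.5, 0.125, 0.03125], n_reps=15, seed=0,
        compute_semantic=False,
    )
    means = prof.values.groupby("f_d")["J"].mean().sort_index(ascending=False)
    assert means.iloc[0] >= means.iloc[-1] - 0.02
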