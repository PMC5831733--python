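"""Fuzzy c-means, consensus alignment and mode classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echinodev import (
    BI_MODAL,
    EARLY,
    INTERMEDIATE,
    LATE,
    UNCLASSIFIED,
    EchinodevError,
    assign_modes,
    classify_centroid_mode,
    consensus_assignment,
    enumerate_paths,
    fuzzy_cmeans,
)


class TestEnumeratePaths:
    @pytest.mark.parametrize("T, expected", [(2, 3), (3, 9), (4, 27), (5, 81)])
    def test_count_closed_form(self, T, expected):
        count, patterns = enumerate_paths(T)
        assert count == expected == len(patterns)
        assert len(set(patterns)) == count  # exhaustive and distinct
        assert all(len(p) == T - 1 for p in patterns)

    def test_too_few_timepoints(self):
        with pytest.raises(EchinodevError):
            enumerate_paths(1)


class TestFuzzyCMeans:
    def test_single_cluster_is_mean(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 4))
        res = fuzzy_cmeans(X, k=1, m=1.5, seed=0)
        assert np.allclose(res.membership, 1.0)
        assert np.allclose(res.centroids[0], X.mean(axis=0), atol=1e-8)

    def test_equidistant_point_splits_membership(self):
        # two tight clouds; the midpoint is equidistant from both centroids
        X = np.array([[0.0, 0.0], [0.0, 0.0], [2.0, 0.0], [2.0, 0.0], [1.0, 0.0]])
        res = fuzzy_cmeans(X, k=2, m=2.0, max_iter=500, seed=1)
        mid = res.membership[-1]
        assert mid[0] == pytest.approx(0.5, abs=1e-6)
        assert mid[1] == pytest.approx(0.5, abs=1e-6)

    def test_membership_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        X = rng.random((200, 4))
        res = fuzzy_cmeans(X, k=27, m=1.25, seed=3)
        assert np.allclose(res.membership.sum(axis=1), 1.0, atol=1e-9)
        assert res.membership.min() >= 0.0 and res.membership.max() <= 1.0

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(4)
        X = rng.random((150, 4))
        res = fuzzy_cmeans(X, k=10, m=1.5, seed=4)
        hist = np.array(res.objective_history)
        assert (np.diff(hist) <= 1e-9 * np.maximum(hist[:-1], 1.0)).all()

    def test_coincident_point_gets_crisp_membership(self):
        X = np.vstack([np.zeros((5, 3)), np.ones((5, 3))])
        res = fuzzy_cmeans(X, k=2, m=1.2, seed=0)
        # every point sits exactly on a converged centroid
        assert np.allclose(np.sort(res.membership.max(axis=1)), 1.0)

    def test_hard_assignment_matches_kmeans_oracle(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(11)
        X = np.vstack(
            [rng.normal(0.0, 0.15, size=(100, 4)), rng.normal(3.0, 0.15, size=(100, 4))]
        )
        res = fuzzy_cmeans(X, k=2, m=1.1, seed=5)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        ours, theirs = res.hard_labels(), km.labels_
        same = (ours == theirs).mean()
        assert max(same, 1 - same) == 1.0  # identical up to label swap

    def test_n_below_k_rejected(self):
        with pytest.raises(EchinodevError):
            fuzzy_cmeans(np.ones((5, 4)), k=6)

    def test_nan_input_rejected(self):
        X = np.ones((10, 4))
        X[0, 0] = np.nan
        with pytest.raises(EchinodevError):
            fuzzy_cmeans(X, k=2)


class TestConsensus:
    def _runs(self, n=60, k=3, runs=5, seed=0):
        rng = np.random.default_rng(seed)
        centers = np.array([[0, 0, 0, 0], [3, 3, 3, 3], [6, 0, 6, 0]], dtype=float)
        X = np.vstack([rng.normal(c, 0.1, size=(n // 3, 4)) for c in centers])
        return [fuzzy_cmeans(X, k=k, m=1.3, seed=seed + r) for r in range(runs)]

    def test_identical_runs_full_support(self):
        runs = self._runs(runs=1) * 4
        cons = consensus_assignment(runs)
        assert np.allclose(cons.consensus_support, 1.0)
        assert (cons.consensus_label == runs[0].hard_labels()).all()

    def test_invariant_under_label_permutation(self):
        runs = self._runs(runs=4)
        cons_a = consensus_assignment(runs)
        # permute cluster indices of every run after the first
        import copy

        permuted = [runs[0]]
        rng = np.random.default_rng(9)
        for r in runs[1:]:
            perm = rng.permutation(r.k)
            r2 = copy.deepcopy(r)
            r2.centroids = r.centroids[perm]
            r2.membership = r.membership[:, perm]
            permuted.append(r2)
        cons_b = consensus_assignment(permuted)
        assert (cons_a.consensus_label == cons_b.consensus_label).all()
        assert np.allclose(cons_a.consensus_support, cons_b.consensus_support)

    def test_majority_rule_two_of_three(self):
        runs = self._runs(runs=3)
        # flip one gene's membership in exactly one run
        import copy

        flipped = copy.deepcopy(runs)
        m = flipped[2].membership
        m[0] = np.roll(m[0], 1)
        cons = consensus_assignment(flipped)
        base = consensus_assignment(runs)
        assert cons.consensus_label[0] == base.consensus_label[0]
        assert cons.consensus_support[0] == pytest.approx(2 / 3)

    def test_mismatched_k_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 4))
        a = fuzzy_cmeans(X, k=2, seed=0)
        b = fuzzy_cmeans(X, k=3, seed=0)
        with pytest.raises(EchinodevError):
            consensus_assignment([a, b])


class TestModeClassification:
    @pytest.mark.parametrize(
        "centroid, expected",
        [
            ((1.0, 0.6, 0.3, 0.2), EARLY),  # single peak at the first stage
            ((0.2, 0.3, 0.6, 1.0), LATE),  # increasing to the last stage
            ((0.2, 1.0, 0.4, 0.3), INTERMEDIATE),  # peak at the second stage
            ((0.2, 0.3, 1.0, 0.4), INTERMEDIATE),  # peak at the third stage
            ((1.0, 0.3, 0.8, 0.2), BI_MODAL),  # two peaks
            ((0.3, 1.0, 0.2, 0.9), BI_MODAL),
            ((0.5, 0.5, 0.5, 0.5), UNCLASSIFIED),  # flat
            ((0.0, 0.0, 0.0, 0.0), UNCLASSIFIED),
        ],
    )
    def test_mode_rules(self, centroid, expected):
        assert classify_centroid_mode(np.array(centroid)) == expected

    def test_flat_eps_suppresses_wobble(self):
        wobble = np.array([1.0, 0.98, 1.0, 0.99])
        assert classify_centroid_mode(wobble, flat_eps=0.05) == UNCLASSIFIED
        assert classify_centroid_mode(wobble, flat_eps=0.0) == BI_MODAL

    def test_wrong_length_rejected(self):
        with pytest.raises(EchinodevError):
            classify_centroid_mode(np.array([1.0, 2.0, 3.0]))

    @given(st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=4, max_size=4))
    @settings(max_examples=200, deadline=None)
    def test_always_returns_a_single_mode(self, values):
        mode = classify_centroid_mode(np.array(values))
        assert mode in {EARLY, INTERMEDIATE, LATE, BI_MODAL, UNCLASSIFIED}


class TestAssignModes:
    def test_genes_inherit_cluster_mode(self):
        runs = TestConsensus()._runs(runs=3)
        cons = consensus_assignment(runs)
        centroids = np.array(
            [[1.0, 0.6, 0.3, 0.2], [0.2, 0.3, 0.6, 1.0], [0.2, 1.0, 0.4, 0.3]]
        )
        mm = assign_modes(cons, centroids=centroids)
        modes_by_cluster = {0: EARLY, 1: LATE, 2: INTERMEDIATE}
        for gene, label in enumerate(cons.consensus_label):
            assert mm.labels.iloc[gene] == modes_by_cluster[label]

    def test_low_expression_unclassified(self):
        runs = TestConsensus()._runs(runs=3)
        cons = consensus_assignment(runs)
        centroids = np.tile([0.2, 0.3, 0.6, 1.0], (3, 1))
        traj = np.ones((len(cons.consensus_label), 4))
        traj[0] = 1e-6  # below the floor
        mm = assign_modes(cons, centroids=centroids, expression=traj, min_expression=1e-3)
        assert mm.labels.iloc[0] == UNCLASSIFIED
        assert (mm.labels.iloc[1:] == LATE).all()
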