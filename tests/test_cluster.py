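"""Dependent t-maps, cluster formation, and sign-flip permutation inference."""

import itertools

import numpy as np
import pytest
from scipy import stats

from conflictlab.cluster import (
    dependent_t_map,
    find_clusters,
    permutation_test,
)

CHAIN_ADJ = {"a": ["b"], "b": ["a", "c"], "c": ["b"], "d": []}
CHAIN_CH = ["a", "b", "c", "d"]


def brute_force_t(stack):
    """Independent textbook recomputation via scipy."""
    return stats.ttest_1samp(stack, 0.0, axis=0).statistic


def flood_fill_oracle(t_map, adj_idx, threshold):
    """Exhaustive recursive partition of supra-threshold points."""
    n_ch, n_t = t_map.shape
    labels = -np.ones((n_ch, n_t), dtype=int)
    next_label = 0
    for sign in (1, -1):
        supra = (sign * t_map) > threshold
        for c in range(n_ch):
            for t in range(n_t):
                if supra[c, t] and labels[c, t] < 0:
                    stack = [(c, t)]
                    labels[c, t] = next_label
                    while stack:
                        cc, tt = stack.pop()
                        for nc in adj_idx[cc]:
                            if supra[nc, tt] and labels[nc, tt] < 0:
                                labels[nc, tt] = next_label
                                stack.append((nc, tt))
                        for nt in (tt - 1, tt + 1):
                            if 0 <= nt < n_t and supra[cc, nt] and labels[cc, nt] < 0:
                                labels[cc, nt] = next_label
                                stack.append((cc, nt))
                    next_label += 1
    return labels


class TestDependentTMap:
    def test_hand_computed_value(self):
        stack = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        assert dependent_t_map(stack)[0, 0] == pytest.approx(2 * np.sqrt(3))

    def test_all_zero_maps_give_zero_t(self):
        t = dependent_t_map(np.zeros((4, 2, 3)))
        assert np.all(t == 0.0)

    def test_matches_textbook_formula(self, rng):
        stack = rng.standard_normal((12, 5, 7))
        mine = dependent_t_map(stack)
        assert np.max(np.abs(mine - brute_force_t(stack))) < 1e-12

    def test_zero_variance_nonzero_mean_warns_inf(self):
        stack = np.ones((3, 1, 1))
        with pytest.warns(UserWarning, match="zero variance"):
            t = dependent_t_map(stack)
        assert np.isinf(t[0, 0])

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            dependent_t_map(np.zeros((1, 2, 2)))


class TestFindClusters:
    def test_isolated_point_single_cluster(self):
        t_map = np.zeros((4, 5))
        t_map[0, 2] = 4.0
        clusters = find_clusters(t_map, CHAIN_ADJ, CHAIN_CH, threshold=2.0)
        assert len(clusters) == 1
        assert clusters[0].members == [(0, 2)]
        assert clusters[0].mass == pytest.approx(4.0)

    def test_nonadjacent_channels_form_two_clusters(self):
        t_map = np.zeros((4, 5))
        t_map[0, 2] = 4.0  # channel a
        t_map[3, 2] = 4.0  # channel d (no neighbours)
        clusters = find_clusters(t_map, CHAIN_ADJ, CHAIN_CH, threshold=2.0)
        assert len(clusters) == 2

    def test_temporal_contiguity_joins_points(self):
        t_map = np.zeros((4, 5))
        t_map[1, 1] = t_map[1, 2] = 3.0
        clusters = find_clusters(t_map, CHAIN_ADJ, CHAIN_CH, threshold=2.0)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 2

    def test_opposite_signs_never_merge(self):
        t_map = np.zeros((4, 5))
        t_map[1, 1], t_map[1, 2] = 3.0, -3.0
        clusters = find_clusters(t_map, CHAIN_ADJ, CHAIN_CH, threshold=2.0)
        assert len(clusters) == 2
        assert {c.sign for c in clusters} == {1, -1}

    def test_partition_matches_flood_fill_oracle(self, rng):
        adj_idx = [[1], [0, 2], [1], []]
        for _ in range(20):
            t_map = rng.standard_normal((4, 10)) * 2.0
            clusters = find_clusters(t_map, CHAIN_ADJ, CHAIN_CH, threshold=2.0)
            labels = flood_fill_oracle(t_map, adj_idx, 2.0)
            mine = {frozenset(c.members) for c in clusters}
            theirs = {
                frozenset(zip(*np.nonzero(labels == k)))
                for k in range(labels.max() + 1)
            }
            assert mine == theirs

    def test_asymmetric_adjacency_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            find_clusters(
                np.zeros((2, 2)), {"a": ["b"], "b": []}, ["a", "b"], 2.0
            )


class TestPermutationTest:
    def exhaustive_oracle(self, stack, adj, ch, threshold):
        """Brute-force null of max |cluster mass| over all sign flips."""
        n = stack.shape[0]
        null = []
        for signs in itertools.product((1, -1), repeat=n):
            flipped = stack * np.array(signs, float)[:, None, None]
            t = stats.ttest_1samp(flipped, 0.0, axis=0).statistic
            t = np.nan_to_num(t)
            cl = find_clusters(t, adj, ch, threshold)
            null.append(max((abs(c.mass) for c in cl), default=0.0))
        return np.array(null)

    def test_auto_exhaustive_matches_independent_enumeration(self, rng):
        stack = rng.standard_normal((6, 4, 8)) + 0.7
        res = permutation_test(
            stack, CHAIN_ADJ, CHAIN_CH, np.arange(8) / 125.0, n_perm=500, seed=0
        )
        assert res.config["method"] == "exhaustive"
        threshold = res.config["threshold"]
        null = self.exhaustive_oracle(stack, CHAIN_ADJ, CHAIN_CH, threshold)
        assert len(null) == 2**6
        for c in res.clusters:
            assert c.p_value == pytest.approx(np.mean(null >= abs(c.mass)))

    def test_sampled_p_close_to_exhaustive(self, rng):
        stack = rng.standard_normal((5, 3, 6)) + 1.0
        kwargs = dict(
            adjacency={"a": ["b"], "b": ["a", "c"], "c": ["b"]},
            ch_names=["a", "b", "c"],
            times=np.arange(6) / 125.0,
        )
        exact = permutation_test(stack, method="exhaustive", seed=0, **kwargs)
        sampled = permutation_test(
            stack, method="sampling", n_perm=10_000, seed=1, **kwargs
        )
        for ce, cs in zip(exact.clusters, sampled.clusters):
            assert cs.p_value == pytest.approx(ce.p_value, abs=0.02)

    def test_p_values_never_zero(self, rng):
        stack = rng.standard_normal((8, 2, 4)) + 5.0  # overwhelming effect
        res = permutation_test(
            stack,
            {"a": [], "b": []},
            ["a", "b"],
            np.arange(4) / 125.0,
            seed=0,
        )
        assert all(c.p_value > 0 for c in res.clusters)

    def test_channel_relabelling_invariance(self, rng):
        stack = rng.standard_normal((7, 3, 5)) + 0.8
        adj = {"a": ["b"], "b": ["a", "c"], "c": ["b"]}
        ch = ["a", "b", "c"]
        res1 = permutation_test(stack, adj, ch, np.arange(5) / 125.0, seed=3)
        perm = [2, 0, 1]
        stack2 = stack[:, perm, :]
        ch2 = [ch[i] for i in perm]
        res2 = permutation_test(stack2, adj, ch2, np.arange(5) / 125.0, seed=3)
        p1 = sorted(c.p_value for c in res1.clusters)
        p2 = sorted(c.p_value for c in res2.clusters)
        assert p1 == pytest.approx(p2)

    def test_low_n_perm_refused(self, rng):
        with pytest.raises(ValueError, match="refused"):
            permutation_test(
                np.zeros((4, 2, 2)), {"a": [], "b": []}, ["a", "b"],
                np.arange(2), n_perm=50,
            )

    def test_cluster_summary_report_form(self, rng):
        stack = rng.standard_normal((6, 4, 8)) + 1.0
        res = permutation_test(
            stack, CHAIN_ADJ, CHAIN_CH, np.arange(8) / 125.0, seed=0
        )
        for row in res.summary():
            assert row["start_s"] <= row["end_s"]
            assert 0 < row["p"] <= 1
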