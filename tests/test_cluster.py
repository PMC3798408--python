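import itertools

import numpy as np
import pytest

from stratclust.cluster import (DistanceMatrix, cut_tree, pairwise_distance,
                                pam, pamk_select, pct_change_heights,
                                select_k_heights, silhouette, ward_linkage)


def naive_distance(X, metric):
    """Double-loop reference for the missing-scaled distance."""
    n, m = X.shape
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            both = ~np.isnan(X[i]) & ~np.isnan(X[j])
            s = ((X[i, both] - X[j, both]) ** 2).sum() * m / both.sum()
            d[i, j] = s if metric == "squared_euclidean" else np.sqrt(s)
    return d


def dm_from_points(x, metric="euclidean"):
    return pairwise_distance(np.asarray(x, dtype=float), metric)


class TestPairwiseDistance:
    def test_complete_rows_pythagoras(self):
        D = dm_from_points([[0, 0], [3, 4]])
        assert D.values[0, 1] == pytest.approx(5.0)
        D2 = dm_from_points([[0, 0], [3, 4]], "squared_euclidean")
        assert D2.values[0, 1] == pytest.approx(25.0)

    def test_missing_scaling_rule(self):
        X = np.array([[1.0, np.nan], [0.0, 0.0]])
        D = pairwise_distance(X, "euclidean")
        assert D.values[0, 1] == pytest.approx(np.sqrt(2.0))
        assert D.overlap[0, 1] == 1

    def test_matches_naive_oracle_with_missing(self, rng):
        for _ in range(10):
            X = rng.normal(size=(6, 4))
            X[rng.random((6, 4)) < 0.25] = np.nan
            X[np.isnan(X).all(axis=1), 0] = 0.0
            try:
                for metric in ("euclidean", "squared_euclidean"):
                    D = pairwise_distance(X, metric)
                    np.testing.assert_allclose(D.values, naive_distance(X, metric),
                                               atol=1e-12)
            except ValueError:
                continue  # a pair with zero overlap was drawn

    def test_zero_overlap_pair_rejected(self):
        X = np.array([[1.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="no observed markers"):
            pairwise_distance(X)


def exhaustive_pam_objective(d, k):
    """Best total nearest-medoid distance over all C(n, k) medoid sets."""
    n = d.shape[0]
    return min(d[:, list(meds)].min(axis=1).sum()
               for meds in itertools.combinations(range(n), k))


class TestPAM:
    def test_separated_pairs(self):
        D = dm_from_points([[0.0], [0.1], [10.0], [10.1]])
        res = pam(D, 2)
        labels = res.partition.labels
        assert labels[0] == labels[1] != labels[2] == labels[3]

    def test_k1_is_exhaustive_medoid(self, rng):
        x = rng.normal(size=(9, 3))
        D = pairwise_distance(x)
        res = pam(D, 1)
        assert res.objective == pytest.approx(
            min(D.values[:, j].sum() for j in range(9)))

    def test_matches_exhaustive_search(self, rng):
        # restarted SWAP escapes the rare 1-exchange local optima of plain
        # BUILD+SWAP on tiny instances
        for n, k in [(6, 2), (7, 3), (8, 2), (8, 3)]:
            for _ in range(5):
                x = rng.normal(size=(n, 2))
                D = pairwise_distance(x)
                res = pam(D, k, seed=0, n_restarts=10)
                assert res.objective == pytest.approx(
                    exhaustive_pam_objective(D.values, k), abs=1e-10)

    def test_k_out_of_range(self):
        D = dm_from_points([[0.0], [1.0]])
        with pytest.raises(ValueError):
            pam(D, 2)


def naive_silhouette(d, labels):
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            continue
        a = d[i, own & (np.arange(n) != i)].mean()
        b = min(d[i, labels == c].mean() for c in set(labels) if c != labels[i])
        s[i] = (b - a) / max(a, b)
    return s


class TestSilhouette:
    def test_hand_computed_values(self):
        D = dm_from_points([[0.0], [1.0], [10.0]])
        res = silhouette(D, np.array([1, 1, 2]))
        assert res.widths[0] == pytest.approx(1 - 1 / 10)
        assert res.widths[2] == 0.0  # singleton convention

    def test_tight_cluster_near_one(self):
        D = dm_from_points([[0.0], [0.0], [50.0], [50.0]])
        res = silhouette(D, np.array([1, 1, 2, 2]))
        assert np.all(res.widths > 0.99)

    def test_matches_bruteforce(self, rng):
        for _ in range(10):
            x = rng.normal(size=(10, 3))
            labels = rng.integers(1, 4, size=10)
            if len(set(labels)) < 2:
                continue
            D = pairwise_distance(x)
            res = silhouette(D, labels)
            np.testing.assert_allclose(res.widths,
                                       naive_silhouette(D.values, labels),
                                       atol=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import silhouette_samples

        x = rng.normal(size=(20, 4))
        labels = rng.integers(1, 4, size=20)
        D = pairwise_distance(x)
        ours = silhouette(D, labels).widths
        ref = silhouette_samples(D.values, labels, metric="precomputed")
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_single_cluster_rejected(self):
        D = dm_from_points([[0.0], [1.0]])
        with pytest.raises(ValueError):
            silhouette(D, np.array([1, 1]))


class TestPamkSelect:
    def test_three_groups_selected(self):
        pts = [[0.0], [0.2], [0.1], [5.0], [5.1], [5.2], [11.0], [11.1], [11.2]]
        res = pamk_select(dm_from_points(pts), range(2, 6))
        assert res.partition.k == 3
        assert res.avg_silhouette > 0.8

    def test_structureless_width_near_zero(self, rng):
        x = rng.uniform(size=(60, 8))
        res = pamk_select(pairwise_distance(x), range(2, 6))
        assert res.avg_silhouette < 0.15


def ward_sse_oracle(x):
    """Greedy Ward merges recomputed from raw coordinates.

    At each step merge the pair of clusters whose pooled SSE increase is
    smallest; the criterion value equals 2 * delta-SSE, which matches the
    Lance-Williams recurrence applied to squared Euclidean distances of
    singletons.
    """
    clusters = [[i] for i in range(len(x))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                na, nb = len(ca), len(cb)
                mu_a = x[ca].mean(axis=0)
                mu_b = x[cb].mean(axis=0)
                delta = na * nb / (na + nb) * ((mu_a - mu_b) ** 2).sum()
                if best is None or delta < best[0] - 1e-12:
                    best = (delta, a, b)
        delta, a, b = best
        merges.append((sorted(clusters[a] + clusters[b]), 2 * delta))
        clusters = ([clusters[i] for i in range(len(clusters)) if i not in (a, b)]
                    + [clusters[a] + clusters[b]])
    return merges


class TestWard:
    def test_two_singletons_merge_at_squared_distance(self):
        x = np.array([[0.0, 0.0], [3.0, 4.0]])
        dend = ward_linkage(pairwise_distance(x, "squared_euclidean"))
        assert dend.heights[0] == pytest.approx(25.0)

    def test_heights_non_decreasing(self, rng):
        for _ in range(5):
            x = rng.normal(size=(12, 3))
            dend = ward_linkage(pairwise_distance(x, "squared_euclidean"))
            assert np.all(np.diff(dend.heights) >= -1e-10)

    def test_matches_sse_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=(8, 2))
            dend = ward_linkage(pairwise_distance(x, "squared_euclidean"))
            oracle = ward_sse_oracle(x)
            # compare merged member sets and criterion values step by step
            members = {i: [i] for i in range(8)}
            for t in range(7):
                a, b = dend.child_a[t], dend.child_b[t]
                merged = sorted(members[a] + members[b])
                members[8 + t] = merged
                assert merged == oracle[t][0]
                assert dend.heights[t] == pytest.approx(oracle[t][1])

    def test_wrong_metric_rejected(self, rng):
        D = pairwise_distance(rng.normal(size=(5, 2)), "euclidean")
        with pytest.raises(ValueError, match="squared_euclidean"):
            ward_linkage(D)


class TestHeightSelection:
    def make_dend(self, heights):
        n = len(heights) + 1
        from stratclust.cluster import Dendrogram

        return Dendrogram(n=n, child_a=np.arange(n - 1),
                          child_b=np.arange(n, 2 * n - 1),
                          heights=np.asarray(heights, dtype=float),
                          sizes=np.arange(2, n + 1))

    def test_pct_arithmetic(self):
        # h(3)=10 then h(2)=30: +200% going from 3 to 2 clusters
        dend = self.make_dend([1, 2, 5, 10, 30, 40])
        pct = pct_change_heights(dend, 3)
        assert pct[2] == pytest.approx(200.0)

    def test_geometric_heights_constant_pct(self):
        r = 1.5
        dend = self.make_dend([r**i for i in range(8)])
        pct = pct_change_heights(dend, 4)
        assert all(v == pytest.approx(100 * (r - 1)) for v in pct.values())

    def test_spike_selects_following_k(self):
        # percentage change maximal when going from 3 to 2 clusters -> keep 3
        dend = self.make_dend([1, 1.1, 1.2, 1.3, 1.4, 10, 11])
        assert select_k_heights(dend, 5) == 3

    def test_zero_height_reported_missing(self):
        dend = self.make_dend([0.0, 0.0, 1.0, 2.0])
        with pytest.warns(UserWarning, match="undefined"):
            pct = pct_change_heights(dend, 3)
        assert np.isnan(pct[3])


class TestCutTree:
    def test_boundary_cuts(self, rng):
        x = rng.normal(size=(6, 2))
        dend = ward_linkage(pairwise_distance(x, "squared_euclidean"))
        assert cut_tree(dend, 1).labels.max() == 1
        assert cut_tree(dend, 6).labels.max() == 6

    def test_two_group_recovery(self):
        x = np.array([[0.0], [0.1], [0.2], [9.0], [9.1], [9.2]])
        dend = ward_linkage(pairwise_distance(x, "squared_euclidean"))
        labels = cut_tree(dend, 2).labels
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert labels[0] != labels[3]

    def test_sizes_partition_n(self, rng):
        x = rng.normal(size=(9, 2))
        dend = ward_linkage(pairwise_distance(x, "squared_euclidean"))
        for k in range(1, 10):
            labels = cut_tree(dend, k).labels
            assert np.bincount(labels)[1:].sum() == 9
            assert labels.max() == k
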