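"""Clustering, STLSQ (with a brute-force subset oracle), the sparsity sweep,
and candidate-pool filtering."""

import itertools
from types import SimpleNamespace

import numpy as np
import pytest

from templatesig import (cluster_by_phase, collect_candidates, fit_clusters,
                         split_train_test, stlsq, sweep_sparsity,
                         true_coefficients)
from templatesig.config import ClusterConfig, SweepConfig
from templatesig.sindy import lambda_grid
from templatesig.states import circular_phase_distance


class TestSplitTrainTest:
    def test_full_scale_split_sizes(self):
        states = SimpleNamespace(n_samples=14_400)
        pool, test = split_train_test(states, ClusterConfig())
        assert pool.size == 10_800 and test.size == 3600
        assert test[0] == 14_400 - 3600
        # an 800-neighbor cluster spans 7.4% of the clustering pool
        assert round(100 * 800 / pool.size, 1) == 7.4

    def test_too_short_trial_raises(self):
        with pytest.raises(ValueError, match="trial too short"):
            split_train_test(SimpleNamespace(n_samples=7199), ClusterConfig())

    def test_no_overlap(self):
        pool, test = split_train_test(SimpleNamespace(n_samples=9000),
                                      ClusterConfig(n_train_centroids=600,
                                                    k=800))
        assert np.intersect1d(pool, test).size == 0


class TestClusterByPhase:
    def test_degenerate_constant_phase(self):
        psi = np.full(50, 42.0)
        labels = np.array(["SS_R"] * 50)
        cs = cluster_by_phase(psi, labels, np.arange(50), 5, 10)
        for c in cs.clusters:
            assert c.centroid_phase == pytest.approx(42.0)
            assert c.members.size == 10

    def test_members_match_brute_force_and_form_an_arc(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            psi = rng.uniform(0, 100, 200)
            labels = np.array(["SS_R"] * 200)
            pool = np.arange(200)
            k = 25
            cs = cluster_by_phase(psi, labels, pool, 10, k)
            order = np.argsort(psi)
            pos = np.empty(200, int)
            pos[order] = np.arange(200)
            for c in cs.clusters:
                d = circular_phase_distance(psi, psi[c.seed])
                expected = set(np.lexsort((pool, d))[:k].tolist())
                assert set(c.members.tolist()) == expected
                # members occupy a contiguous arc of the circular ordering
                ring = np.sort(pos[c.members])
                gaps = np.diff(np.concatenate([ring, [ring[0] + 200]]))
                assert (gaps > 1).sum() <= 1

    def test_wraparound_collects_both_ends(self):
        psi = np.concatenate([np.linspace(98.5, 99.9, 10),
                              np.linspace(0.1, 1.5, 10),
                              np.linspace(45, 55, 30)])
        labels = np.array(["SS_R"] * 50)
        cs = cluster_by_phase(psi, labels, np.arange(50), 1, 15)
        members = cs.clusters[0].members  # seeded at psi = 98.5
        assert (psi[members] > 90).any() and (psi[members] < 10).any()

    def test_k_exceeding_pool_raises(self):
        with pytest.raises(ValueError, match="exceeds pool"):
            cluster_by_phase(np.zeros(10), np.array(["SS_R"] * 10),
                             np.arange(10), 2, 11)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        psi = rng.uniform(0, 100, 300)
        labels = np.array(["SS_R"] * 300)
        a = cluster_by_phase(psi, labels, np.arange(300), 20, 50)
        b = cluster_by_phase(psi, labels, np.arange(300), 20, 50)
        for ca, cb in zip(a.clusters, b.clusters):
            assert np.array_equal(ca.members, cb.members)


class TestStlsq:
    def test_lambda_zero_is_ordinary_least_squares(self):
        rng = np.random.default_rng(1)
        theta = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        expected, *_ = np.linalg.lstsq(theta, y, rcond=None)
        assert np.allclose(stlsq(theta, y, 0.0), expected)

    def test_lambda_above_max_gives_empty_model(self):
        rng = np.random.default_rng(2)
        theta = rng.normal(size=(40, 4))
        y = theta @ np.array([1.0, -0.5, 0.2, 0.0])
        ols, *_ = np.linalg.lstsq(theta, y, rcond=None)
        assert np.all(stlsq(theta, y, np.abs(ols).max() * 1.01) == 0.0)

    def test_exact_sparse_recovery(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(size=(50, 3))
        y = 2.0 * theta[:, 0]
        assert np.allclose(stlsq(theta, y, 0.5), [2.0, 0.0, 0.0], atol=1e-12)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            stlsq(np.ones((3, 1)), np.ones(3), -1.0)

    def test_matches_exhaustive_subset_oracle(self):
        """On 200 random 4-6-column systems, STLSQ lands on the
        threshold-stable subset with minimal residual, found by exhaustive
        enumeration."""
        rng = np.random.default_rng(12345)
        for _ in range(200):
            p = rng.integers(4, 7)
            theta = rng.normal(size=(60, p))
            true = np.zeros(p)
            kk = rng.integers(1, p)
            idx = rng.choice(p, size=kk, replace=False)
            true[idx] = rng.uniform(1.0, 3.0, kk) * rng.choice([-1, 1], kk)
            y = theta @ true + rng.normal(0, 0.05, 60)
            lam = float(rng.uniform(0.3, 0.8))
            got = frozenset(np.flatnonzero(stlsq(theta, y, lam)).tolist())
            best, best_rss = frozenset(), float(y @ y)
            for r in range(1, p + 1):
                for S in itertools.combinations(range(p), r):
                    c, *_ = np.linalg.lstsq(theta[:, S], y, rcond=None)
                    if np.all(np.abs(c) >= lam):
                        rss = float(np.sum((theta[:, S] @ c - y) ** 2))
                        if rss < best_rss - 1e-12:
                            best, best_rss = frozenset(S), rss
            assert got == best


class TestSweepSparsity:
    def test_lambda_grid_is_log_spaced_with_correct_endpoints(self):
        grid = lambda_grid(10.0, SweepConfig())
        assert grid.size == 40
        assert grid[0] == pytest.approx(0.1)
        assert grid[-1] == pytest.approx(10.0)
        ratios = grid[1:] / grid[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_largest_lambda_keeps_at_most_one_term(self):
        rng = np.random.default_rng(7)
        theta = rng.normal(size=(80, 6))
        y = theta @ np.array([3.0, 1.0, 0, 0, 0.5, 0]) + rng.normal(0, 0.1, 80)
        supports = sweep_sparsity(theta, y)
        xi_full, *_ = np.linalg.lstsq(theta, y, rcond=None)
        lam_max = np.abs(xi_full).max()
        for sup, lams in supports.items():
            if any(np.isclose(l, lam_max) for l in lams):
                assert len(sup) <= 1

    def test_true_support_appears_for_stance_cluster(self, params,
                                                     canonical_states,
                                                     canonical_library):
        """Ground-truth SLIP stance clusters yield the true support
        {kappa_L, kappa_L*L0~} for an interior lambda range."""
        states, lib = canonical_states, canonical_library
        idx = np.flatnonzero(states.gait_phase == "SS_R")[:400]
        rows = lib.rows_for_samples(idx)
        supports = sweep_sparsity(lib.theta[rows], lib.target[rows])
        true_sup = frozenset(
            np.flatnonzero(true_coefficients(params, {"R"})).tolist())
        assert true_sup in supports


class TestCollectCandidates:
    def _clusters(self, n, label="SS_R"):
        from templatesig.sindy import Cluster, ClusterSet
        cl = [Cluster(seed=i, members=np.arange(5), centroid_phase=0.0,
                      centroid_gait_phase=label) for i in range(n)]
        return ClusterSet(clusters=cl, k=5, pool_idx=np.arange(5))

    def test_exact_threshold_boundary(self):
        n = 3600
        common, rare, boundary = frozenset({0, 1}), frozenset({2}), frozenset({3})
        per_cluster = []
        for i in range(n):
            d = {common: [1.0]}
            if i < 36:
                d[boundary] = [2.0]  # exactly 1% -> retained
            if i < 35:
                d[rare] = [3.0]  # below 1% -> discarded
            per_cluster.append(d)
        kept = collect_candidates(per_cluster, self._clusters(n), 0.01)
        keys = {c.key for c in kept}
        assert common in keys and boundary in keys and rare not in keys
        by_key = {c.key: c for c in kept}
        assert by_key[boundary].frequency == pytest.approx(0.01)

    def test_frequencies_sum_to_at_least_one(self):
        rng = np.random.default_rng(9)
        n = 50
        per_cluster = [{frozenset({int(rng.integers(0, 3))}): [1.0]}
                       for _ in range(n)]
        kept = collect_candidates(per_cluster, self._clusters(n), 0.01)
        assert sum(c.frequency for c in kept) >= 1.0

    def test_empty_pool_raises(self):
        # every support recurs in well under half the clusters
        per_cluster = [{frozenset({i % 13}): [1.0]} for i in range(200)]
        with pytest.raises(ValueError, match="no frequent"):
            collect_candidates(per_cluster, self._clusters(200), 0.5)
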