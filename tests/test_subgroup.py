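"""SCV covariances, modularity, clustering and the Gershgorin detector."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from fsig.subgroup import (REST, GershgorinSubgroupDetector, SCVCluster,
                           cluster_scvs, gershgorin_subgroups, modularity,
                           scv_covariance, stack_scvs)


def planted_block_matrix(K, blocks, background=0.0):
    """(C, labels) for disjoint planted blocks [(indices, rho), ...]."""
    C = np.full((K, K), background)
    labels = np.full(K, REST, dtype=int)
    for b, (idx, rho) in enumerate(blocks):
        idx = np.asarray(idx)
        C[np.ix_(idx, idx)] = rho
        labels[idx] = b
    np.fill_diagonal(C, 1.0)
    return C, labels


def oracle_block_count(blocks, r_min=0.0):
    """Closed form: a block of g subjects at correlation rho contributes one
    eigenvalue 1 + (g-1)*rho; it is detected iff that exceeds r_min + 1."""
    return sum(1 for idx, rho in blocks if 1 + (len(idx) - 1) * rho > r_min + 1)


class TestSCVCovariance:
    def test_identical_rows_give_all_ones(self):
        y = np.random.default_rng(0).standard_normal(500)
        C = scv_covariance(np.vstack([y, y, y]))
        np.testing.assert_allclose(C, 1.0)

    def test_orthogonal_rows_give_identity(self):
        Y = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        np.testing.assert_allclose(scv_covariance(Y), np.eye(2), atol=1e-12)

    def test_matches_sample_correlation(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((2, 2000))
        Y[1] = 0.6 * Y[0] + 0.8 * Y[1]
        np.testing.assert_allclose(scv_covariance(Y), np.corrcoef(Y), atol=1e-12)

    def test_properties(self):
        rng = np.random.default_rng(2)
        C = scv_covariance(rng.standard_normal((6, 300)))
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert np.all(np.abs(C) <= 1.0)
        assert np.min(np.linalg.eigvalsh(C)) > -1e-8

    def test_constant_row_rejected(self):
        Y = np.vstack([np.ones(100), np.random.default_rng(3).standard_normal(100)])
        with pytest.raises(ValueError):
            scv_covariance(Y)


class TestStackSCVs:
    def test_sign_alignment_removes_negative_blocks(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(1000)
        # three subjects share component 0 up to sign
        Ys = [np.vstack([s * base + 0.1 * rng.standard_normal(1000),
                         rng.standard_normal(1000)])
              for s in (1.0, -1.0, 1.0)]
        raw = stack_scvs(Ys)[0]
        aligned = stack_scvs(Ys, sign_align_refs=base[None, :])[0]
        assert np.min(scv_covariance(raw.Y)) < -0.9
        assert np.min(scv_covariance(aligned.Y)) > 0.9

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            stack_scvs([np.random.default_rng(5).standard_normal((2, 50))])


class TestModularity:
    def test_two_disconnected_equal_blocks(self):
        C, labels = planted_block_matrix(8, [(range(4), 0.8),
                                             (range(4, 8), 0.8)])
        assert modularity(C, labels) == pytest.approx(0.5)

    def test_single_community_is_zero(self):
        C, _ = planted_block_matrix(8, [(range(4), 0.8), (range(4, 8), 0.8)])
        assert modularity(C, np.zeros(8)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_networkx(self):
        """Dual-route check against the graph-library implementation."""
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(6)
        C = scv_covariance(rng.standard_normal((7, 200)))
        labels = rng.integers(0, 3, 7)
        A = np.abs(C).copy()
        np.fill_diagonal(A, 0.0)
        G = nx.from_numpy_array(A)
        comms = [set(np.where(labels == c)[0]) for c in np.unique(labels)]
        expected = nx.community.modularity(G, comms, weight="weight")
        assert modularity(C, labels) == pytest.approx(expected, abs=1e-12)

    def test_true_labels_beat_random_shuffles(self):
        C, labels = planted_block_matrix(10, [(range(5), 0.8),
                                              (range(5, 10), 0.8)])
        q_true = modularity(C, labels)
        rng = np.random.default_rng(7)
        for _ in range(100):
            assert modularity(C, rng.permutation(labels)) <= q_true + 1e-12

    def test_zero_weight_graph(self):
        assert modularity(np.eye(4), [0, 1, 2, 3]) == 0.0


class TestGershgorinDetector:
    def test_identity_has_no_subgroups(self):
        p = gershgorin_subgroups(np.eye(5))
        assert p.r_min == 0.0
        assert p.n_subgroups == 0
        assert np.all(p.membership == REST)

    def test_single_block_closed_form_spectrum(self):
        """Block of 3 at rho=0.8 among 6: eigenvalues {1+2rho, 1, 1, 1,
        1-rho, 1-rho} and exactly the block members detected."""
        C, labels = planted_block_matrix(6, [(range(3), 0.8)])
        p = gershgorin_subgroups(C)
        np.testing.assert_allclose(sorted(p.eigenvalues),
                                   [0.2, 0.2, 1, 1, 1, 2.6], atol=1e-12)
        assert p.n_subgroups == 1
        np.testing.assert_array_equal(p.membership, labels)

    def test_two_equal_blocks_with_degenerate_eigenvalues(self):
        """Two size-3 blocks at the same rho share an eigenvalue; membership
        must still match the planted structure exactly."""
        C, labels = planted_block_matrix(8, [(range(3), 0.9),
                                             (range(3, 6), 0.9)])
        for assign in ("joint", "per_eigenvector"):
            p = gershgorin_subgroups(C, assign=assign)
            assert p.n_subgroups == 2
            assert adjusted_rand_score(labels, p.membership) == 1.0

    def test_noiseless_oracle_equivalence(self):
        """B and memberships match the planted structure (and the closed-form
        eigenvalue count) on random noiseless block configurations."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            K = int(rng.integers(7, 13))
            sizes = []
            remaining = K - 1  # keep at least one background subject
            while remaining >= 3 and len(sizes) < 3 and rng.random() < 0.8:
                g = int(rng.integers(3, min(remaining, 6) + 1))
                sizes.append(g)
                remaining -= g
            if not sizes:
                sizes = [3]
                remaining = K - 4
            blocks, start = [], 0
            for g in sizes:
                blocks.append((range(start, start + g),
                               float(rng.uniform(0.5, 0.95))))
                start += g
            C, labels = planted_block_matrix(K, blocks)
            p = gershgorin_subgroups(C)
            assert p.n_subgroups == oracle_block_count(blocks)
            assert adjusted_rand_score(labels, p.membership) == 1.0
            np.testing.assert_array_equal(np.sort(labels[p.membership >= 0]),
                                          np.sort(p.membership[p.membership >= 0]))

    def test_noise_robustness(self):
        """Planted memberships survive background correlation noise
        (mean adjusted Rand >= 0.9 over 20 seeds)."""
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            C, labels = planted_block_matrix(12, [(range(4), 0.7),
                                                  (range(4, 8), 0.6)])
            E = rng.normal(0.0, 0.05, (12, 12))
            E = (E + E.T) / 2
            np.fill_diagonal(E, 0.0)
            p = gershgorin_subgroups(np.clip(C + E, -1, 1))
            scores.append(adjusted_rand_score(labels, p.membership))
        assert np.mean(scores) >= 0.9

    def test_permutation_equivariance(self):
        C, labels = planted_block_matrix(9, [(range(3), 0.8),
                                             (range(3, 6), 0.6)])
        rng = np.random.default_rng(9)
        perm = rng.permutation(9)
        p1 = gershgorin_subgroups(C)
        p2 = gershgorin_subgroups(C[np.ix_(perm, perm)])
        assert adjusted_rand_score(p1.membership[perm], p2.membership) == 1.0

    def test_contract_violations_raise(self):
        with pytest.raises(ValueError):
            gershgorin_subgroups(np.arange(9.0).reshape(3, 3))
        bad = np.eye(3)
        bad[0, 0] = 2.0
        with pytest.raises(ValueError):
            gershgorin_subgroups(bad)

    def test_estimator_api(self):
        C, labels = planted_block_matrix(6, [(range(3), 0.8)])
        det = GershgorinSubgroupDetector().fit(C)
        assert det.n_subgroups_ == 1
        np.testing.assert_array_equal(det.labels_, labels)
        np.testing.assert_array_equal(det.fit_predict(C), labels)
        # block order groups members first
        assert set(det.block_order_[:3]) == {0, 1, 2}


class TestClusterSCVs:
    def _patterned_covs(self, rng):
        def noisy(C):
            E = rng.normal(0, 0.02, C.shape)
            E = (E + E.T) / 2
            np.fill_diagonal(E, 0.0)
            out = np.clip(C + E, -1, 1)
            np.fill_diagonal(out, 1.0)
            return out
        A, _ = planted_block_matrix(10, [(range(4), 0.8)])
        B, _ = planted_block_matrix(10, [(range(5, 9), 0.7)])
        return [noisy(A) for _ in range(3)] + [noisy(B) for _ in range(3)]

    def test_single_candidate_gives_overall_mean(self):
        rng = np.random.default_rng(10)
        covs = self._patterned_covs(rng)
        res = cluster_scvs(covs, [1], seed=0)
        assert res.n_clusters == 1
        expected = np.mean(covs, axis=0)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(res.aggregated[0], expected)

    def test_two_patterns_recovered(self):
        rng = np.random.default_rng(11)
        covs = self._patterned_covs(rng)
        res = cluster_scvs(covs, [2], seed=0)
        a = res.assignments
        assert len(set(a[:3])) == 1 and len(set(a[3:])) == 1 and a[0] != a[3]

    def test_duplicates_share_assignment(self):
        rng = np.random.default_rng(12)
        covs = self._patterned_covs(rng)
        res = cluster_scvs(covs + [covs[0].copy()], [2], seed=0)
        assert res.assignments[-1] == res.assignments[0]

    def test_estimator_api(self):
        rng = np.random.default_rng(13)
        covs = self._patterned_covs(rng)
        est = SCVCluster(candidate_I=(1, 2, 3), seed=0).fit(np.array(covs))
        assert est.n_clusters_ in (1, 2, 3)
        assert len(est.aggregated_) == est.n_clusters_
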