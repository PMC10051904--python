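"""Constraint machinery and the constrained (c-EBM) fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fsig.constrained import (ReferenceSet, augmented_row_cost, cebm_fit,
                              constrained_row_gradient, constraint_value,
                              similarity, update_multiplier)
from fsig.ica import _random_orthogonal, decoupling_vector, ica_ebm_fit, whiten
from tests.conftest import make_gennorm_sources


class TestSimilarity:
    def test_self_and_negated_self(self):
        rng = np.random.default_rng(0)
        r = rng.standard_normal(500)
        assert similarity(r, r) == pytest.approx(1.0)
        assert similarity(r, -r) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        v = np.array([1.0, -1.0, 1.0, -1.0])
        w = np.array([1.0, 1.0, -1.0, -1.0])
        assert similarity(v, w) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            similarity(np.ones(10), np.arange(10.0))


class TestConstraintValue:
    def test_plug_in_examples(self):
        rng = np.random.default_rng(1)
        r = rng.standard_normal(1000)
        assert constraint_value(0.3, r, r) == pytest.approx(-0.7)
        r0 = np.array([1.0, -1.0, 1.0, -1.0])
        y0 = np.array([1.0, 1.0, -1.0, -1.0])
        assert constraint_value(0.3, r0, y0) == pytest.approx(0.3, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_theta_zero_always_satisfied(self, seed):
        rng = np.random.default_rng(seed)
        r, y = rng.standard_normal((2, 200))
        assert constraint_value(0.0, r, y) <= 0.0

    def test_theta_range_enforced(self):
        with pytest.raises(ValueError):
            constraint_value(1.5, np.arange(5.0), np.arange(5.0))


class TestMultiplierUpdate:
    @pytest.mark.parametrize("mu,h,gamma,expected", [
        (0.0, -0.2, 3.0, 0.0),
        (0.5, 0.1, 1.0, 0.6),
        (0.2, -0.05, 3.0, 0.05),
    ])
    def test_plug_in(self, mu, h, gamma, expected):
        assert update_multiplier(mu, h, gamma) == pytest.approx(expected)

    def test_satisfied_constraint_drives_mu_to_zero(self):
        mu = 1.0
        for _ in range(100):
            mu = update_multiplier(mu, -0.2, 3.0)
            assert mu >= 0.0
        assert mu == 0.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            update_multiplier(-0.1, 0.0, 1.0)
        with pytest.raises(ValueError):
            update_multiplier(0.1, 0.0, 0.0)


class TestConstrainedGradient:
    def _setup(self, seed=0, V=3000):
        rng = np.random.default_rng(seed)
        S = make_gennorm_sources([0.6, 1.0, 3.0, 8.0], V, rng)
        A = rng.standard_normal((4, 4))
        data = whiten(A @ S, 4)
        r = S[0] + 0.5 * rng.standard_normal(V)
        return rng, data.X, r

    def test_matches_finite_differences(self, table):
        """Analytic gradient vs central differences of the augmented cost."""
        rng, X, r = self._setup()
        h = 1e-6
        for _ in range(10):
            w = rng.standard_normal(4)
            w /= np.linalg.norm(w)
            W = np.vstack([w, rng.standard_normal((3, 4))])
            d = decoupling_vector(W, 0)
            theta, mu, gamma = rng.uniform(0.2, 0.9), rng.uniform(0, 1), 3.0
            g = constrained_row_gradient(w, X, d, r, mu, gamma, table,
                                         theta=theta)
            fd = np.empty(4)
            for j in range(4):
                e = np.zeros(4)
                e[j] = h
                fd[j] = (augmented_row_cost(w + e, X, d, r, theta, mu, gamma, table)
                         - augmented_row_cost(w - e, X, d, r, theta, mu, gamma, table)
                         ) / (2 * h)
            assert np.linalg.norm(g - fd) < 1e-4 * np.linalg.norm(fd)

    def test_inactive_penalty_equals_unconstrained_gradient(self, table):
        """With the constraint far satisfied the penalty term vanishes and
        the gradient is the plain decoupled one."""
        rng, X, r = self._setup(seed=3)
        w = rng.standard_normal(4)
        W = np.vstack([w, rng.standard_normal((3, 4))])
        d = decoupling_vector(W, 0)
        # reference equal to the current estimate: epsilon = 1, h = theta - 1 < 0
        y = w @ X
        g_con = constrained_row_gradient(w, X, d, y, 0.0, 3.0, table, theta=0.3)
        from fsig.ica import _row_cost, _row_grad
        c, info = _row_cost(w, X, d, table)
        g_unc = _row_grad(w, X, d, table, info)
        np.testing.assert_array_equal(g_con, g_unc)

    def test_reference_sign_flip_leaves_gradient_unchanged(self, table):
        """epsilon = |corr(r, y)| is even in r: flipping the reference flips
        both sign(corr) and d corr/dw, so the constraint term (and the whole
        gradient) is invariant — the constraint cannot prefer a sign."""
        rng, X, r = self._setup(seed=4)
        w = rng.standard_normal(4)
        W = np.vstack([w, rng.standard_normal((3, 4))])
        d = decoupling_vector(W, 0)
        kw = dict(mu_n=0.9, gamma=3.0, theta=0.9)
        g_plus = constrained_row_gradient(w, X, d, r, table=table, **kw)
        g_minus = constrained_row_gradient(w, X, d, -r, table=table, **kw)
        np.testing.assert_allclose(g_plus, g_minus, atol=1e-12)
        # and the sign-sensitive inner factor alone is antisymmetric
        c_plus = augmented_row_cost(w, X, d, r, 0.9, 0.9, 3.0, table)
        c_minus = augmented_row_cost(w, X, d, -r, 0.9, 0.9, 3.0, table)
        assert c_plus == pytest.approx(c_minus, abs=1e-12)

    def test_degenerate_direction_raises(self, table):
        _, X, r = self._setup(seed=5)
        w = np.array([1.0, 0, 0, 0])
        d = np.array([0.0, 1.0, 0, 0])
        with pytest.raises(ZeroDivisionError):
            constrained_row_gradient(w, X, d, r, 0.0, 3.0, table)


class TestReferenceSet:
    def test_normalization_and_labels(self):
        rng = np.random.default_rng(6)
        R = rng.standard_normal((2, 300)) + 5.0
        refs = ReferenceSet(R, labels=["a", "b"])
        assert refs.R.shape == (2, 300)
        np.testing.assert_allclose(refs.R.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(refs.R, axis=1), 1.0)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            ReferenceSet(np.ones((1, 50)))

    def test_duplicate_references_rejected(self):
        r = np.random.default_rng(7).standard_normal(100)
        with pytest.raises(ValueError):
            ReferenceSet(np.vstack([r, 2 * r]))


@pytest.fixture(scope="module")
def problem():
    """Subject whose sources correlate ~0.8 with the references."""
    rng = np.random.default_rng(42)
    S = make_gennorm_sources([0.6, 1.0, 3.0, 8.0], 5000, rng)
    A = rng.standard_normal((4, 4))
    data = whiten(A @ S, 4)
    R = np.vstack([S[0] + 0.7 * rng.standard_normal(5000),
                   S[1] + 0.7 * rng.standard_normal(5000)])
    return {"data": data, "refs": ReferenceSet(R), "S": S, "A": A}


class TestCebmFit:
    def test_feasible_constraints_satisfied(self, problem, table):
        dem, con = cebm_fit(problem["data"], problem["refs"], theta=0.3,
                            table=table, seed=7)
        assert np.all(con.satisfied)
        assert np.all(con.epsilon >= 0.3)
        assert np.all(con.mu >= 0.0)

    def test_theta_zero_matches_unconstrained_from_shared_init(self, problem,
                                                               table):
        W0 = _random_orthogonal(4, np.random.default_rng(3))
        state_u = ica_ebm_fit(problem["data"], table, seed=7, W0=W0)
        dem, _ = cebm_fit(problem["data"], problem["refs"], theta=0.0,
                          table=table, seed=7, W0=W0)
        C = np.abs(np.corrcoef(np.vstack([state_u.Y, dem.Y]))[:4, 4:])
        assert np.all(C.max(axis=1) > 0.999)

    def test_mean_epsilon_monotone_in_theta(self, problem, table):
        means = []
        for th in (0.0, 0.3, 0.6, 0.9):
            _, con = cebm_fit(problem["data"], problem["refs"], theta=th,
                              table=table, seed=7)
            means.append(con.epsilon.mean())
        assert np.all(np.diff(means) >= -1e-9)

    def test_components_align_across_subjects(self, problem, table):
        """Two subjects fitted independently produce components that match
        the references in the same order."""
        rng = np.random.default_rng(43)
        S2 = make_gennorm_sources([0.6, 1.0, 3.0, 8.0], 5000, rng)
        S2[0] = 0.8 * problem["S"][0] + 0.6 * S2[0]
        S2[1] = 0.8 * problem["S"][1] + 0.6 * S2[1]
        S2 = (S2 - S2.mean(1, keepdims=True)) / S2.std(1, ddof=1, keepdims=True)
        data2 = whiten(rng.standard_normal((4, 4)) @ S2, 4)
        for data, seed in ((problem["data"], 7), (data2, 8)):
            dem, _ = cebm_fit(data, problem["refs"], theta=0.3, table=table,
                              seed=seed)
            for n in range(2):
                cors = [abs(np.corrcoef(problem["refs"].R[k], dem.Y[n])[0, 1])
                        for k in range(2)]
                assert int(np.argmax(cors)) == n

    def test_subject_order_independence(self, problem, table):
        """Per-subject fits with per-subject seeds do not interact."""
        d1, _ = cebm_fit(problem["data"], problem["refs"], theta=0.3,
                         table=table, seed=7)
        # fit another subject in between, then refit the first
        rng = np.random.default_rng(44)
        other = whiten(rng.standard_normal((4, 4)) @
                       make_gennorm_sources([0.6, 1.0, 3.0, 8.0], 5000, rng), 4)
        cebm_fit(other, problem["refs"], theta=0.3, table=table, seed=99)
        d1_again, _ = cebm_fit(problem["data"], problem["refs"], theta=0.3,
                               table=table, seed=7)
        np.testing.assert_array_equal(d1.W, d1_again.W)

    def test_too_many_references_rejected(self, problem, table):
        rng = np.random.default_rng(45)
        refs5 = ReferenceSet(rng.standard_normal((5, 5000)))
        with pytest.raises(ValueError):
            cebm_fit(problem["data"], refs5, table=table)

    def test_estimator_wrapper(self, problem, table):
        from fsig.constrained import ConstrainedICAEBM
        X = problem["data"].X.T
        est = ConstrainedICAEBM(references=problem["refs"], theta=0.3,
                                random_state=7, max_sweeps=128,
                                tol=1e-5).fit(X)
        assert est.epsilon_.shape == (2,)
        assert np.all(est.satisfied_)
        assert est.sources_.shape == (5000, 4)
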