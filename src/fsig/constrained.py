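"""Constrained EBM (c-EBM): reference-guided ICA via an augmented Lagrangian.

Each constrained source estimate ``y_n`` is tied to a spatial reference map
``r_n`` through the inequality

    h_n = theta_n - |corr(r_n, y_n)| <= 0,

i.e. the absolute Pearson correlation between estimate and reference must
reach at least ``theta_n``.  The inequality enters the decoupled ICA-EBM row
cost through the standard augmented-Lagrangian construction (a slack
variable eliminated analytically into the max form)

    J_n^c = J_n + ( max(0, gamma*h_n + mu_n)^2 - mu_n^2 ) / (2*gamma),

with multiplier update ``mu_n <- max(0, gamma*h_n + mu_n)`` once per sweep.

Because every subject is fitted independently against the *same* references,
constrained components come out aligned across subjects (component n matches
reference n), which is what makes the per-component cross-subject stacking
of the subgroup stage meaningful without any post-hoc matching.

Lower ``theta`` preserves more inter-subject variability; higher ``theta``
pulls estimates toward the references.  The pipeline default is
``theta = 0.3``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.utils.validation import check_is_fitted

from .entropy import EntropyBoundTable, default_table
from .ica import (DemixingState, ICAEBM, SubjectData, _fit_rows, _row_cost,
                  _row_grad, _sign_fix, _random_orthogonal, decoupling_vector,
                  whiten)

__all__ = [
    "ReferenceSet",
    "ConstraintState",
    "similarity",
    "constraint_value",
    "update_multiplier",
    "constrained_row_gradient",
    "augmented_row_cost",
    "cebm_fit",
    "ConstrainedICAEBM",
]

DEFAULT_THETA = 0.3
DEFAULT_GAMMA = 3.0


@dataclass
class ReferenceSet:
    """Spatial reference maps (one per constrained component).

    Rows are zero-meaned and unit-normed on construction.  Reference k
    constrains component k; components beyond ``n_references`` are left
    unconstrained.
    """

    R: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        R = np.atleast_2d(np.asarray(self.R, dtype=float))
        R = R - R.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(R, axis=1)
        if np.any(norms == 0):
            raise ValueError("a reference map is constant (zero variance)")
        self.R = R / norms[:, None]
        if not self.labels:
            self.labels = [f"ref{i}" for i in range(R.shape[0])]
        if len(self.labels) != R.shape[0]:
            raise ValueError("labels length must match number of references")
        C = np.abs(self.R @ self.R.T)
        np.fill_diagonal(C, 0.0)
        if np.any(C >= 1.0 - 1e-12):
            raise ValueError("two references are perfectly correlated")

    @property
    def n_references(self) -> int:
        return self.R.shape[0]

    @property
    def n_samples(self) -> int:
        return self.R.shape[1]

    def standardized(self) -> np.ndarray:
        """References rescaled to unit sample variance (ddof=1), zero mean."""
        V = self.R.shape[1]
        return self.R * np.sqrt(V - 1)


@dataclass
class ConstraintState:
    """Constraint-side diagnostics of a c-EBM fit."""

    theta: np.ndarray
    mu: np.ndarray
    gamma: float
    epsilon: np.ndarray
    epsilon_trace: np.ndarray
    satisfied: np.ndarray


def similarity(r: np.ndarray, y: np.ndarray) -> float:
    """Absolute Pearson correlation between a reference and an estimate."""
    r = np.asarray(r, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if r.shape != y.shape:
        raise ValueError("reference and estimate must have equal length")
    rc = r - r.mean()
    yc = y - y.mean()
    nr, ny = np.linalg.norm(rc), np.linalg.norm(yc)
    if nr == 0 or ny == 0:
        raise ValueError("similarity undefined for zero-variance input")
    return float(abs(rc @ yc) / (nr * ny))


def constraint_value(theta: float, r: np.ndarray, y: np.ndarray) -> float:
    """Inequality constraint ``h = theta - similarity(r, y)``; satisfied iff <= 0."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    return theta - similarity(r, y)


def update_multiplier(mu: float, h: float, gamma: float) -> float:
    """Augmented-Lagrangian multiplier update ``max(0, gamma*h + mu)``."""
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return max(0.0, gamma * h + mu)


def _standardize_reference(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float).ravel()
    rc = r - r.mean()
    sd = rc.std(ddof=1)
    if sd == 0:
        raise ValueError("reference has zero variance")
    return rc / sd


def augmented_row_cost(w_n, X, d_n, r_n, theta, mu_n, gamma,
                       table: EntropyBoundTable | None = None) -> float:
    """Augmented-Lagrangian decoupled row cost (constraint penalty included)."""
    if table is None:
        table = default_table()
    r_std = _standardize_reference(r_n)
    c, _ = _row_cost(np.asarray(w_n, float), X, np.asarray(d_n, float), table,
                     r_std=r_std, theta=theta, mu=mu_n, gamma=gamma)
    return c


def constrained_row_gradient(w_n, X, d_n, r_n, mu_n, gamma,
                             table: EntropyBoundTable | None = None,
                             theta: float = DEFAULT_THETA) -> np.ndarray:
    """Exact gradient of the augmented decoupled row cost.

    Sum of (a) the negentropy term, (b) the decoupling term ``-d_n/(d_n.w_n)``
    and (c) the constraint term
    ``-max(0, gamma*h + mu) * sign(corr) * d eps/d w`` — identically zero when
    the penalty is inactive.  Matches central finite differences of
    :func:`augmented_row_cost` (the estimate is standardized inside the cost,
    so the gradient carries the corresponding chain-rule terms).
    """
    if table is None:
        table = default_table()
    w_n = np.asarray(w_n, dtype=float)
    d_n = np.asarray(d_n, dtype=float)
    if float(d_n @ w_n) == 0.0:
        raise ZeroDivisionError("degenerate direction: d_n . w_n == 0")
    r_std = _standardize_reference(r_n)
    kw = dict(r_std=r_std, theta=theta, mu=mu_n, gamma=gamma)
    c, info = _row_cost(w_n, X, d_n, table, **kw)
    if info is None:
        raise ZeroDivisionError("degenerate direction: d_n . w_n == 0")
    return _row_grad(w_n, X, d_n, table, info, **kw)


def _reference_init(X: np.ndarray, refs_std: np.ndarray, N: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Initial demixing matrix with constrained rows seeded by the references.

    Row n (n < N_ref) starts at the projection of reference n onto the
    whitened data space, so each constrained row begins already correlated
    with its reference; this fixes the component-to-reference assignment from
    the first sweep and avoids the deadlock where row-wise descent settles on
    a permutation in which another row occupies the referenced source.
    Remaining rows span a random orthonormal basis of the complement.
    """
    V = X.shape[1]
    n_ref = refs_std.shape[0]
    W0 = np.zeros((N, N))
    P = X @ refs_std.T / (V - 1)
    for n in range(n_ref):
        nrm = np.linalg.norm(P[:, n])
        W0[n] = P[:, n] / nrm if nrm > 0 else _random_orthogonal(N, rng)[n]
    if n_ref < N:
        q, _ = np.linalg.qr(W0[:n_ref].T if n_ref else
                            np.zeros((N, 0)), mode="complete")
        comp = q[:, n_ref:]
        rot = _random_orthogonal(N - n_ref, rng)
        W0[n_ref:] = (comp @ rot).T
    return W0


def cebm_fit(data: SubjectData, refs: ReferenceSet,
             theta: float | Sequence[float] = DEFAULT_THETA,
             gamma: float = DEFAULT_GAMMA,
             table: EntropyBoundTable | None = None,
             seed: int | None = None, max_iterations: int = 512,
             tolerance: float = 1e-6, W0: np.ndarray | None = None,
             ) -> tuple[DemixingState, ConstraintState]:
    """Fit c-EBM on one whitened subject against shared reference maps.

    Row-wise optimization as in plain ICA-EBM, with the augmented-Lagrangian
    penalty on rows 0..N_ref-1 (reference k constrains component k) and one
    multiplier update per sweep.  Constrained components are returned in
    reference order and sign-aligned to their references; unconstrained
    components follow with the skewness sign convention.
    """
    X = data.X
    if not np.all(np.isfinite(X)):
        raise ValueError("input data contains NaN or infinite values")
    N = X.shape[0]
    if refs.n_references > N:
        raise ValueError(
            f"{refs.n_references} references exceed model order {N}")
    if refs.n_samples != X.shape[1]:
        raise ValueError("references and data must share the sample grid")
    if table is None:
        table = default_table()
    rng = np.random.default_rng(seed)
    refs_std = refs.standardized()
    if W0 is None:
        W0 = _reference_init(X, refs_std, N, rng)
    W, diag = _fit_rows(X, table, rng, W0=W0, max_sweeps=max_iterations,
                        tol=tolerance, refs_std=refs_std, theta=theta,
                        gamma=gamma)
    if not diag["converged"]:
        warnings.warn(f"c-EBM did not converge in {max_iterations} sweeps "
                      f"for subject '{data.subject_id}'", RuntimeWarning)
    Y = W @ X
    Y /= Y.std(axis=1, ddof=1, keepdims=True)
    # sign: constrained rows follow their reference, the rest follow skewness
    n_ref = refs.n_references
    eps = np.empty(n_ref)
    for n in range(n_ref):
        rho = float(refs_std[n] @ Y[n]) / (X.shape[1] - 1)
        eps[n] = abs(rho)
        if rho < 0:
            Y[n] *= -1.0
            W[n] *= -1.0
    if n_ref < N:
        _sign_fix(Y[n_ref:], W[n_ref:])
    D = np.vstack([decoupling_vector(W, n) for n in range(N)])
    dem = DemixingState(W=W, Y=Y, decoupling_vectors=D,
                        cost_trace=diag["cost_trace"],
                        converged=diag["converged"],
                        iterations=diag["sweeps"], seed=seed)
    con = ConstraintState(theta=diag["theta"], mu=diag["mu"], gamma=gamma,
                          epsilon=eps, epsilon_trace=diag["eps_trace"],
                          satisfied=eps >= diag["theta"] - 1e-9)
    return dem, con


class ConstrainedICAEBM(ICAEBM):
    """c-EBM as a scikit-learn transformer.

    Parameters are those of :class:`~fsig.ica.ICAEBM` plus the reference
    maps (``references``, shape (n_refs, n_samples) or a
    :class:`ReferenceSet`), the constraint parameter ``theta`` (scalar or
    per-component) and the augmented-Lagrangian learning rate ``gamma``.

    Extra fitted attributes: ``epsilon_`` (final |corr| per constrained
    component), ``satisfied_``, ``mu_``, ``constraint_state_``.
    """

    def __init__(self, references=None, theta=DEFAULT_THETA,
                 gamma=DEFAULT_GAMMA, n_components=None, max_sweeps=512,
                 tol=1e-6, random_state=None, grid_resolution=512):
        super().__init__(n_components=n_components, max_sweeps=max_sweeps,
                         tol=tol, random_state=random_state,
                         grid_resolution=grid_resolution)
        self.references = references
        self.theta = theta
        self.gamma = gamma

    def fit(self, X, y=None):
        from sklearn.utils.validation import check_array

        X = check_array(X, dtype=float)
        if self.references is None:
            raise ValueError("ConstrainedICAEBM requires reference maps")
        refs = (self.references if isinstance(self.references, ReferenceSet)
                else ReferenceSet(np.asarray(self.references, dtype=float)))
        n_comp = self.n_components or X.shape[1]
        data = whiten(X.T, n_comp)
        state, cstate = cebm_fit(data, refs, theta=self.theta,
                                 gamma=self.gamma, table=self._table(),
                                 seed=self.random_state,
                                 max_iterations=self.max_sweeps,
                                 tolerance=self.tol)
        self._finalize(X, data, state)
        self.constraint_state_ = cstate
        self.epsilon_ = cstate.epsilon
        self.satisfied_ = cstate.satisfied
        self.mu_ = cstate.mu
        return self
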