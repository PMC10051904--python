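"""ICA by entropy bound minimization (ICA-EBM) with non-orthogonal decoupling.

The linear ICA model is ``x(v) = A s(v)`` with ``N`` independent zero-mean,
unit-variance sources observed at ``V`` samples (voxels, for spatial fMRI
ICA).  A demixing matrix ``W`` is sought so that ``y = W x`` are maximally
independent; the mutual-information cost separates into per-row problems

    J_n(w_n) = -negentropy(y_n) - log|d_n^T w_n|,

where ``d_n`` is the *decoupling vector* — the unit vector orthogonal to all
rows of ``W`` except row n — which replaces the log-determinant term and lets
each row be optimized on its own without constraining ``W`` to be orthogonal.
The negentropy is the EBM estimator of :mod:`fsig.entropy`.

Optimization is cyclic row-wise gradient descent with a backtracking
(Armijo) line search on the decoupled cost; rows are kept unit-norm on
whitened data so each estimate has unit variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .entropy import (EntropyBoundTable, HALF_LOG_2PIE, MEASURING_FUNCTIONS,
                      default_table)

__all__ = [
    "SubjectData",
    "DemixingState",
    "whiten",
    "decoupling_vector",
    "decoupled_cost",
    "ica_ebm_fit",
    "ICAEBM",
]


@dataclass
class SubjectData:
    """One subject's dimension-reduced, whitened data matrix.

    ``X`` is N x V with (1/(V-1)) X X^T = I; ``whitening_transform`` maps the
    raw (zero-meaned) P x V data to X, and ``dewhitening_transform`` maps
    back for spatial-map reconstruction.
    """

    X: np.ndarray
    subject_id: str = ""
    whitening_transform: Optional[np.ndarray] = None
    dewhitening_transform: Optional[np.ndarray] = None
    row_means: Optional[np.ndarray] = None
    mask_reference: Optional[object] = None

    @property
    def n_components(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]


@dataclass
class DemixingState:
    """Result of a single-dataset ICA-EBM fit.

    ``W`` (N x N) acts on whitened data; ``Y = W X`` has unit-variance rows.
    ``cost_trace`` has shape (n_sweeps, N, 2): per sweep and row, the
    decoupled cost before and after that row's accepted update (after <=
    before for every accepted line-search step).
    """

    W: np.ndarray
    Y: np.ndarray
    decoupling_vectors: np.ndarray
    cost_trace: np.ndarray
    converged: bool
    iterations: int
    seed: Optional[int] = None
    m_star: Optional[np.ndarray] = None


def whiten(raw: np.ndarray, n_components: int, subject_id: str = "",
           mask_reference=None) -> SubjectData:
    """PCA-whiten a raw P x V matrix down to ``n_components`` rows.

    Rows are zero-meaned internally; the output satisfies
    ``(1/(V-1)) X X^T = I``.  Raises if the requested order exceeds the
    numerical rank of the data.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw data must be a 2-D matrix (channels x samples)")
    P, V = raw.shape
    if n_components > P:
        raise ValueError(f"n_components={n_components} exceeds {P} channels")
    means = raw.mean(axis=1, keepdims=True)
    Xc = raw - means
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(P, V) * np.finfo(float).eps))
    if n_components > rank:
        raise ValueError(
            f"requested n_components={n_components} but data rank is {rank}")
    s = s[:n_components]
    U = U[:, :n_components]
    # scale so the ddof=1 sample covariance of the output is the identity
    T = (np.sqrt(V - 1) / s)[:, None] * U.T
    X = T @ Xc
    return SubjectData(X=X, subject_id=subject_id, whitening_transform=T,
                       dewhitening_transform=U * (s / np.sqrt(V - 1)),
                       row_means=means, mask_reference=mask_reference)


def decoupling_vector(W: np.ndarray, n: int) -> np.ndarray:
    """Unit vector orthogonal to every row of ``W`` except row ``n``.

    Spans the null space of the (N-1) x N matrix of the other rows; the sign
    is chosen so that ``d_n . w_n > 0``.
    """
    W = np.asarray(W, dtype=float)
    N = W.shape[0]
    others = np.delete(W, n, axis=0)
    # null space via QR of the transposed submatrix
    q, r = np.linalg.qr(others.T, mode="complete")
    diag = np.abs(np.diag(r)) if r.size else np.array([])
    if others.size and (diag.size < N - 1 or
                        np.min(diag) < 1e-12 * max(1.0, np.max(diag))):
        raise np.linalg.LinAlgError(
            f"demixing matrix is degenerate: rows other than {n} are rank deficient")
    d = q[:, -1]
    proj = float(d @ W[n])
    if proj < 0:
        d = -d
    return d


# ---------------------------------------------------------------------------
# Decoupled row cost / gradient engine (optionally with a reference penalty)
# ---------------------------------------------------------------------------


def _row_cost(w, X, d, table, r_std=None, theta=0.0, mu=0.0, gamma=3.0):
    """Decoupled (optionally augmented-Lagrangian constrained) row cost.

    ``y = w^T X`` is standardized internally; the cost is
    ``-negentropy(y_hat) - log|d.w|`` plus, when a standardized reference
    ``r_std`` is given, ``(max(0, gamma*h + mu)^2 - mu^2) / (2*gamma)`` with
    ``h = theta - |corr(r, y)|``.

    Returns (cost, info dict) where info carries the quantities the gradient
    reuses.  A zero ``d.w`` yields an infinite-cost sentinel.
    """
    V = X.shape[1]
    z = w @ X
    sigma = np.linalg.norm(z) / np.sqrt(V - 1)
    if sigma <= 0:
        return np.inf, None
    yhat = z / sigma
    neg, mom = table.negentropy_terms(yhat)
    m_star = int(np.argmax(neg)) + 1
    dw = float(d @ w)
    if dw == 0.0:
        return np.inf, None
    cost = -neg[m_star - 1] - np.log(abs(dw))
    info = {"yhat": yhat, "sigma": sigma, "m_star": m_star,
            "moments": mom, "dw": dw, "eps": None}
    if r_std is not None:
        rho = float(r_std @ yhat) / (V - 1)
        eps = abs(rho)
        h = theta - eps
        a = max(0.0, gamma * h + mu)
        cost = cost + (a * a - mu * mu) / (2.0 * gamma)
        info.update(rho=rho, eps=eps, h=h, active=a)
    return float(cost), info


def _row_grad(w, X, d, table, info, r_std=None, theta=0.0, mu=0.0, gamma=3.0):
    """Exact gradient of :func:`_row_cost` with respect to ``w``.

    Because the cost standardizes ``y`` internally, the negentropy and
    constraint terms carry chain-rule corrections along ``Chat w`` (with
    ``Chat`` the sample covariance of X); on whitened unit-norm rows these
    reduce to the classic EBM/c-EBM update terms.
    """
    V = X.shape[1]
    yhat = info["yhat"]
    sigma = info["sigma"]
    m_star = info["m_star"]
    mf = MEASURING_FUNCTIONS[m_star - 1]
    q = X @ (w @ X) / (V - 1)          # Chat w
    gy = mf.derivative(yhat)
    dt_dw = ((X @ gy) / V - np.mean(gy * yhat) * q) / sigma
    Oprime = table.bound_derivative(m_star, info["moments"][m_star - 1])
    grad = Oprime * dt_dw - d / info["dw"]
    if r_std is not None and info["active"] > 0.0:
        rho = info["rho"]
        drho_dw = ((X @ r_std) / (V - 1) - rho * q) / sigma
        grad = grad - info["active"] * np.sign(rho) * drho_dw
    return grad


def decoupled_cost(w_n: np.ndarray, data: SubjectData, d_n: np.ndarray,
                   table: EntropyBoundTable | None = None) -> tuple[float, int]:
    """Decoupled ICA-EBM cost of one demixing row, in nats.

    Returns ``(cost, m_star)``: ``-negentropy(y_n) - log|d_n.w_n|`` with the
    estimate standardized to unit variance, and the selected measuring
    function.  ``d_n.w_n == 0`` returns ``(inf, 0)``.
    """
    if table is None:
        table = default_table()
    w_n = np.asarray(w_n, dtype=float)
    if not np.any(w_n):
        raise ValueError("w_n must be nonzero")
    cost, info = _row_cost(w_n, data.X, np.asarray(d_n, dtype=float), table)
    return (cost, 0) if info is None else (cost, info["m_star"])


def _random_orthogonal(N: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((N, N)))
    return q * np.sign(np.diag(r))


def _sign_fix(Y: np.ndarray, W: np.ndarray) -> None:
    """Deterministic sign convention: flip each source so its skewness is
    positive (fallback: the largest-magnitude sample is positive)."""
    for n in range(Y.shape[0]):
        y = Y[n]
        sk = np.mean(y**3)
        s = np.sign(sk) if abs(sk) > 1e-3 else np.sign(y[np.argmax(np.abs(y))])
        if s < 0:
            Y[n] *= -1.0
            W[n] *= -1.0


def _fit_rows(X, table, rng, W0=None, max_sweeps=512, tol=1e-6,
              refs_std=None, theta=None, gamma=3.0, mu0=None):
    """Cyclic decoupled row optimization shared by ICA-EBM and c-EBM.

    ``refs_std``: optional (N_ref x V) standardized references constraining
    rows 0..N_ref-1.  Returns (W, diagnostics dict).
    """
    N, V = X.shape
    W = _random_orthogonal(N, rng) if W0 is None else np.array(W0, dtype=float)
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    n_ref = 0 if refs_std is None else refs_std.shape[0]
    theta_vec = np.zeros(n_ref)
    if n_ref and theta is not None:
        theta_vec = np.broadcast_to(np.asarray(theta, dtype=float), (n_ref,)).copy()
    mu = np.zeros(n_ref) if mu0 is None else np.array(mu0, dtype=float)

    cost_trace = []
    eps_trace = []
    alpha = np.ones(N)
    converged = False
    sweeps = 0
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        W_old = W.copy()
        sweep_costs = np.empty((N, 2))
        for n in range(N):
            d = decoupling_vector(W, n)
            w = W[n]
            constrained = n < n_ref
            kw = dict(r_std=refs_std[n] if constrained else None,
                      theta=theta_vec[n] if constrained else 0.0,
                      mu=mu[n] if constrained else 0.0, gamma=gamma)
            c0, info = _row_cost(w, X, d, table, **kw)
            sweep_costs[n] = (c0, c0)
            if info is None:
                continue
            g = _row_grad(w, X, d, table, info, **kw)
            g_t = g - (g @ w) * w        # tangential part on the unit sphere
            gnorm2 = float(g_t @ g_t)
            if gnorm2 < 1e-24:
                continue
            a = min(max(alpha[n] * 2.0, 1e-10), 1.0)
            accepted = False
            while a >= 1e-12:
                w_try = w - a * g
                nrm = np.linalg.norm(w_try)
                if nrm > 0:
                    w_try = w_try / nrm
                    c1, _ = _row_cost(w_try, X, d, table, **kw)
                    if c1 <= c0 - 1e-4 * a * gnorm2:
                        accepted = True
                        break
                a *= 0.5
            if accepted:
                W[n] = w_try
                alpha[n] = a
                sweep_costs[n, 1] = c1
        # multiplier update, once per sweep
        sweep_eps = np.empty(n_ref)
        for n in range(n_ref):
            y = W[n] @ X
            y = y / (np.linalg.norm(y) / np.sqrt(V - 1))
            eps = abs(float(refs_std[n] @ y) / (V - 1))
            sweep_eps[n] = eps
            h = theta_vec[n] - eps
            mu[n] = max(0.0, gamma * h + mu[n])
        cost_trace.append(sweep_costs)
        eps_trace.append(sweep_eps)
        delta = float(np.max(1.0 - np.abs(np.sum(W * W_old, axis=1))))
        if delta < tol:
            converged = True
            break

    diag = {"converged": converged, "sweeps": sweeps,
            "cost_trace": (np.asarray(cost_trace) if cost_trace
                           else np.empty((0, N, 2))),
            "eps_trace": (np.asarray(eps_trace) if eps_trace
                          else np.empty((0, n_ref))),
            "mu": mu, "theta": theta_vec}
    return W, diag


def _total_cost(W, X, table):
    total = 0.0
    for n in range(W.shape[0]):
        d = decoupling_vector(W, n)
        c, _ = _row_cost(W[n], X, d, table)
        total += c
    return total


def ica_ebm_fit(data: SubjectData, table: EntropyBoundTable | None = None,
                seed: int | None = None, max_iterations: int = 512,
                tolerance: float = 1e-6, W0: np.ndarray | None = None,
                n_init: int = 1) -> DemixingState:
    """Fit single-dataset ICA-EBM on whitened data.

    Cyclically optimizes each demixing row by gradient descent with a
    backtracking line search on the decoupled cost, re-deriving the
    decoupling vector at every row visit.  Convergence is declared when
    ``max_n (1 - |w_n_new . w_n_old|) < tolerance``; otherwise the state is
    returned with ``converged=False`` and a warning.  ``n_init`` restarts
    from fresh seeded initializations and keeps the solution with the lowest
    total decoupled cost (row-wise descent can stall in local optima that
    leave a source pair mixed).
    """
    X = data.X
    if not np.all(np.isfinite(X)):
        raise ValueError("input data contains NaN or infinite values")
    if table is None:
        table = default_table()
    rng = np.random.default_rng(seed)
    if max_iterations == 0:
        N = X.shape[0]
        W = _random_orthogonal(N, rng) if W0 is None else np.array(W0, dtype=float)
        W /= np.linalg.norm(W, axis=1, keepdims=True)
        Y = W @ X
        Y /= Y.std(axis=1, ddof=1, keepdims=True)
        D = np.vstack([decoupling_vector(W, n) for n in range(N)])
        return DemixingState(W=W, Y=Y, decoupling_vectors=D,
                             cost_trace=np.empty((0, N, 2)), converged=False,
                             iterations=0, seed=seed)
    W = diag = None
    best = np.inf
    for init in range(max(1, n_init)):
        W_i, diag_i = _fit_rows(X, table, rng, W0=W0 if init == 0 else None,
                                max_sweeps=max_iterations, tol=tolerance)
        cost_i = _total_cost(W_i, X, table)
        if cost_i < best:
            best, W, diag = cost_i, W_i, diag_i
    if not diag["converged"]:
        warnings.warn(
            f"ICA-EBM did not converge in {max_iterations} sweeps",
            RuntimeWarning)
    Y = W @ X
    Y /= Y.std(axis=1, ddof=1, keepdims=True)
    _sign_fix(Y, W)
    N = X.shape[0]
    D = np.vstack([decoupling_vector(W, n) for n in range(N)])
    m_star = np.array([default_m_star(Y[n], table) for n in range(N)])
    return DemixingState(W=W, Y=Y, decoupling_vectors=D,
                         cost_trace=diag["cost_trace"],
                         converged=diag["converged"],
                         iterations=diag["sweeps"], seed=seed, m_star=m_star)


def default_m_star(y: np.ndarray, table: EntropyBoundTable) -> int:
    neg, _ = table.negentropy_terms(y)
    return int(np.argmax(neg)) + 1


class ICAEBM(TransformerMixin, BaseEstimator):
    """ICA by entropy bound minimization, scikit-learn style.

    Follows the :class:`~sklearn.decomposition.FastICA` conventions: ``X`` is
    (n_samples, n_features); ``fit`` whitens to ``n_components`` and runs the
    decoupled EBM optimizer; ``transform`` returns the source estimates.

    Parameters
    ----------
    n_components : int or None
        Model order; defaults to the number of features.
    max_sweeps : int
        Maximum number of cyclic row sweeps.
    tol : float
        Convergence tolerance on ``max_n (1 - |w_n_new . w_n_old|)``.
    random_state : int or None
        Seed for the random orthogonal initialization.
    grid_resolution : int
        Resolution of the entropy bound table.

    Attributes
    ----------
    components_ : (n_components, n_features) unmixing matrix applied to
        centered data; ``S = (X - mean_) @ components_.T``.
    mixing_ : pseudo-inverse of ``components_``.
    demixing_ : (n_components, n_components) demixing matrix in whitened space.
    converged_, n_sweeps_, cost_trace_ : optimizer diagnostics.
    """

    def __init__(self, n_components=None, max_sweeps=512, tol=1e-6,
                 random_state=None, grid_resolution=512, n_init=1):
        self.n_components = n_components
        self.max_sweeps = max_sweeps
        self.tol = tol
        self.random_state = random_state
        self.grid_resolution = grid_resolution
        self.n_init = n_init

    def _table(self):
        return default_table(self.grid_resolution)

    def _fit_state(self, data: SubjectData) -> DemixingState:
        return ica_ebm_fit(data, self._table(), seed=self.random_state,
                           max_iterations=self.max_sweeps, tolerance=self.tol,
                           n_init=self.n_init)

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n_comp = self.n_components or X.shape[1]
        data = whiten(X.T, n_comp)
        state = self._fit_state(data)
        self._finalize(X, data, state)
        return self

    def _finalize(self, X, data, state):
        self.whitening_ = data.whitening_transform
        self.mean_ = data.row_means.ravel()
        self.demixing_ = state.W
        self.components_ = state.W @ data.whitening_transform
        self.mixing_ = np.linalg.pinv(self.components_)
        self.sources_ = state.Y.T
        self.converged_ = state.converged
        self.n_sweeps_ = state.iterations
        self.cost_trace_ = state.cost_trace
        self.state_ = state
        self.n_features_in_ = X.shape[1]

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        S = (X - self.mean_) @ self.components_.T
        return S

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.sources_
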