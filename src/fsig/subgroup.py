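"""Subgroup identification from source component vector (SCV) covariances.

After every subject has been decomposed against the same reference maps, the
n-th *source component vector* stacks component n of all K subjects into a
K x V matrix ``Y_n``; its K x K sample correlation matrix ``C_n`` encodes how
similarly the subjects express that functional network.  Subjects forming a
homogeneous subgroup appear as a high-correlation diagonal block in ``C_n``
(after permutation).

Detection proceeds in two steps:

I.  SCVs with similar cross-subject correlation patterns are clustered
    (k-means on the vectorized upper triangles of their ``C_n``), and each
    cluster is summarized by the mean covariance ``C_bar``; the number of
    clusters is chosen to maximize the modularity of the best partition any
    aggregated matrix supports.

II. The Gershgorin-disc eigenspectrum rule is applied to ``C_bar``: with
    unit diagonal, every Gershgorin disc is centered at 1 with radius
    ``R_i = sum_{j != i} |rho_ij|``; eigenvalues exceeding ``R_min + 1``
    (outside the smallest disc) cannot be explained by a matrix without
    block structure, so their count gives the number of subgroups B and the
    corresponding eigenvectors localize the member subjects.

Membership labels use ``-1`` for the unassigned remainder ("rest") and
``0..B-1`` for subgroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SCVMatrix",
    "SCVClustering",
    "SubgroupPartition",
    "stack_scvs",
    "scv_covariance",
    "cluster_scvs",
    "gershgorin_subgroups",
    "modularity",
    "GershgorinSubgroupDetector",
    "SCVCluster",
    "REST",
]

REST = -1


@dataclass
class SCVMatrix:
    """Component n of every subject, stacked: K x V, rows standardized."""

    Y: np.ndarray
    component_index: int = 0
    subject_ids: list[str] = field(default_factory=list)


@dataclass
class SCVClustering:
    """Step-I result: SCV-to-cluster assignment and aggregated covariances."""

    assignments: np.ndarray
    n_clusters: int
    aggregated: list[np.ndarray]
    modularity_per_I: dict[int, float]
    best_cluster: int
    seed: Optional[int] = None


@dataclass
class SubgroupPartition:
    """Step-II result: Gershgorin radii, outlying eigenvalues and membership."""

    radii: np.ndarray
    r_min: float
    eigenvalues: np.ndarray
    n_subgroups: int
    membership: np.ndarray
    modularity: float
    block_order: np.ndarray


def stack_scvs(states: Sequence, n_components: int | None = None,
               sign_align_refs: np.ndarray | None = None,
               subject_ids: list[str] | None = None) -> list[SCVMatrix]:
    """Stack per-subject source estimates into per-component SCV matrices.

    ``states`` may be DemixingStates or plain (N x V) source arrays.  When
    ``sign_align_refs`` (N_ref x V) is given, each subject row is flipped so
    its correlation with the matching reference is positive before stacking —
    the constraint uses |corr|, so per-subject signs are otherwise arbitrary
    and would plant artificial negative blocks in the covariance.
    """
    mats = [np.asarray(getattr(s, "Y", s), dtype=float) for s in states]
    K = len(mats)
    if K < 2:
        raise ValueError("need at least two subjects")
    N = n_components or mats[0].shape[0]
    ids = subject_ids or [f"subject{k}" for k in range(K)]
    out = []
    for n in range(N):
        Y = np.vstack([m[n] for m in mats])
        Y = Y - Y.mean(axis=1, keepdims=True)
        sd = Y.std(axis=1, ddof=1)
        if np.any(sd == 0):
            bad = ids[int(np.argmin(sd))]
            raise ValueError(f"component {n} of {bad} is constant")
        Y /= sd[:, None]
        if sign_align_refs is not None and n < sign_align_refs.shape[0]:
            r = sign_align_refs[n] - sign_align_refs[n].mean()
            s = np.sign(Y @ r)
            s[s == 0] = 1.0
            Y *= s[:, None]
        out.append(SCVMatrix(Y=Y, component_index=n, subject_ids=ids))
    return out


def scv_covariance(scv: SCVMatrix | np.ndarray) -> np.ndarray:
    """Sample covariance ``(1/(V-1)) Y Y^T`` of an SCV, in correlation form.

    Rows are standardized, so the result has unit diagonal (renormalized
    exactly) and entries in [-1, 1].
    """
    Y = np.asarray(getattr(scv, "Y", scv), dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("SCV must be K x V with V >= 2")
    sd = Y.std(axis=1, ddof=1)
    if np.any(sd == 0):
        raise ValueError(
            f"subject row {int(np.argmin(sd))} is constant; covariance undefined")
    Yc = (Y - Y.mean(axis=1, keepdims=True)) / sd[:, None]
    C = (Yc @ Yc.T) / (Y.shape[1] - 1)
    d = np.sqrt(np.diag(C))
    C /= np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return np.clip((C + C.T) / 2.0, -1.0, 1.0)


def modularity(C: np.ndarray, labels: Sequence) -> float:
    """Newman-Girvan modularity of a subject partition on |rho| edge weights.

    The weighted graph has edges ``|C[i, j]|`` for i != j (diagonal excluded);
    each subgroup is one community and the unassigned remainder forms its own
    single community.  All-zero off-diagonal weight returns 0.
    """
    C = np.asarray(C, dtype=float)
    labels = np.asarray(list(labels))
    if labels.shape[0] != C.shape[0]:
        raise ValueError("labels must cover all subjects")
    A = np.abs(C).astype(float)
    np.fill_diagonal(A, 0.0)
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    k = A.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    Q = (A[same].sum() - (np.outer(k, k)[same].sum()) / two_m) / two_m
    # diagonal i==i pairs belong to their own community: add their null term
    Q -= np.sum(k * k) / (two_m * two_m)
    return float(Q)


def _check_correlation_matrix(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError("covariance must be in correlation form (unit diagonal)")
    return (C + C.T) / 2.0


def gershgorin_subgroups(C: np.ndarray, assign: str = "joint",
                         seed: int = 0) -> SubgroupPartition:
    """Identify homogeneous subject subgroups from a correlation matrix.

    The number of subgroups is the count of eigenvalues strictly greater
    than ``R_min + 1`` where ``R_min`` is the smallest Gershgorin radius
    ``min_i sum_{j != i} |rho_ij|`` (for unit diagonal, all discs are
    centered at 1, so an eigenvalue outside the smallest disc exceeds
    ``R_min + 1``).  Members are found by k-means on the outlying
    eigenvectors:

    - ``assign="joint"`` (default): (B+1)-means on the K x B eigenvector
      rows; same-block subjects have (near-)identical rows, the remainder
      sits near the origin, and the geometry is invariant to rotations
      within degenerate eigenspaces.  The cluster whose centroid is closest
      to the origin is labeled "rest".
    - ``assign="per_eigenvector"``: independent 2-means on each
      eigenvector's absolute loadings; the high-magnitude cluster forms that
      subgroup, overlaps resolved by largest absolute loading.

    ``B = 0`` yields an empty partition with every subject labeled rest (-1).
    """
    C = _check_correlation_matrix(C)
    K = C.shape[0]
    absC = np.abs(C)
    radii = absC.sum(axis=1) - 1.0
    r_min = float(radii.min())
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # strict inequality; the 1e-9 guard keeps eigenvalues that are exactly
    # on the disc boundary up to floating-point noise (e.g. unit eigenvalues
    # of uncorrelated subjects when R_min = 0) from being miscounted
    B = int(np.sum(evals > r_min + 1.0 + 1e-9))
    membership = np.full(K, REST, dtype=int)
    if B > 0:
        U = evecs[:, :B]
        if assign == "joint":
            n_clusters = min(B + 1, K)
            km = KMeans(n_clusters=n_clusters, n_init=20, random_state=seed)
            lab = km.fit_predict(U)
            rest_cluster = int(np.argmin(np.linalg.norm(km.cluster_centers_, axis=1)))
            next_id = 0
            mapping = {}
            for c in range(n_clusters):
                if c == rest_cluster:
                    continue
                mapping[c] = next_id
                next_id += 1
            for i in range(K):
                membership[i] = mapping.get(lab[i], REST)
        elif assign == "per_eigenvector":
            strength = np.full(K, -np.inf)
            for b in range(B):
                load = np.abs(U[:, b])
                km = KMeans(n_clusters=2, n_init=20, random_state=seed)
                lab = km.fit_predict(load[:, None])
                hi = int(np.argmax(km.cluster_centers_.ravel()))
                for i in np.where(lab == hi)[0]:
                    if load[i] > strength[i]:
                        membership[i] = b
                        strength[i] = load[i]
        else:
            raise ValueError("assign must be 'joint' or 'per_eigenvector'")
        # renumber subgroups by first-subject order for determinism
        seen = {}
        out = np.full(K, REST, dtype=int)
        for i in range(K):
            if membership[i] != REST:
                g = membership[i]
                if g not in seen:
                    seen[g] = len(seen)
                out[i] = seen[g]
        membership = out
    Q = modularity(C, membership)
    block_order = np.argsort(np.where(membership == REST, np.iinfo(np.int32).max,
                                      membership), kind="stable")
    return SubgroupPartition(radii=radii, r_min=r_min, eigenvalues=evals,
                             n_subgroups=B, membership=membership,
                             modularity=Q, block_order=block_order)


def cluster_scvs(covariances: Sequence[np.ndarray], candidate_I: Sequence[int],
                 seed: int = 0, assign: str = "joint") -> SCVClustering:
    """Step I: cluster SCV covariance matrices and pick the cluster count.

    For every candidate number of clusters I, k-means (20 seeded restarts)
    runs on the vectorized upper triangles of the covariances; each cluster's
    aggregated mean covariance is scored by the modularity of its
    Gershgorin-based partition, and the (I, cluster) pair with the highest
    modularity wins.
    """
    covs = [np.asarray(c, dtype=float) for c in covariances]
    if len(covs) < 1:
        raise ValueError("need at least one covariance")
    K = covs[0].shape[0]
    iu = np.triu_indices(K, k=1)
    feats = np.vstack([c[iu] for c in covs])
    best = (-np.inf, None, None, None)
    mod_per_I: dict[int, float] = {}
    for I in candidate_I:
        if not 1 <= I <= len(covs):
            raise ValueError(f"candidate I={I} out of range [1, {len(covs)}]")
        if I == 1:
            lab = np.zeros(len(covs), dtype=int)
        else:
            km = KMeans(n_clusters=I, n_init=20, random_state=seed)
            lab = km.fit_predict(feats)
        agg = []
        scores = []
        for c in range(I):
            members = [covs[j] for j in np.where(lab == c)[0]]
            if not members:
                scores.append(-np.inf)
                agg.append(np.eye(K))
                continue
            Cbar = np.mean(members, axis=0)
            np.fill_diagonal(Cbar, 1.0)
            agg.append(Cbar)
            part = gershgorin_subgroups(Cbar, assign=assign, seed=seed)
            scores.append(part.modularity)
        mod_per_I[I] = float(np.max(scores))
        if mod_per_I[I] > best[0]:
            best = (mod_per_I[I], I, lab, (agg, int(np.argmax(scores))))
    _, best_I, lab, (agg, best_cluster) = best
    return SCVClustering(assignments=lab, n_clusters=best_I, aggregated=agg,
                         modularity_per_I=mod_per_I, best_cluster=best_cluster,
                         seed=seed)


class GershgorinSubgroupDetector(ClusterMixin, BaseEstimator):
    """Gershgorin-disc subgroup detector, scikit-learn style.

    ``fit(C)`` takes a K x K subject correlation matrix; fitted attributes
    are ``labels_`` (-1 = rest), ``n_subgroups_``, ``radii_``, ``r_min_``,
    ``eigenvalues_``, ``modularity_`` and ``block_order_``.
    """

    def __init__(self, assign: str = "joint", seed: int = 0):
        self.assign = assign
        self.seed = seed

    def fit(self, X, y=None):
        part = gershgorin_subgroups(np.asarray(X, dtype=float),
                                    assign=self.assign, seed=self.seed)
        self.partition_ = part
        self.labels_ = part.membership
        self.n_subgroups_ = part.n_subgroups
        self.radii_ = part.radii
        self.r_min_ = part.r_min
        self.eigenvalues_ = part.eigenvalues
        self.modularity_ = part.modularity
        self.block_order_ = part.block_order
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class SCVCluster(BaseEstimator):
    """Step-I SCV clustering as an estimator over stacked covariances.

    ``fit(C)`` takes an (n_components, K, K) array (or list) of SCV
    covariance matrices.
    """

    def __init__(self, candidate_I=(1, 2, 3), seed: int = 0,
                 assign: str = "joint"):
        self.candidate_I = candidate_I
        self.seed = seed
        self.assign = assign

    def fit(self, X, y=None):
        covs = list(X)
        res = cluster_scvs(covs, list(self.candidate_I), seed=self.seed,
                           assign=self.assign)
        self.clustering_ = res
        self.labels_ = res.assignments
        self.n_clusters_ = res.n_clusters
        self.aggregated_ = res.aggregated
        self.best_cluster_ = res.best_cluster
        self.modularity_per_I_ = res.modularity_per_I
        return self
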