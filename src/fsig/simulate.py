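"""Synthetic multi-subject fixtures with planted subgroup structure.

Each of ``K`` subjects observes ``N`` statistically independent spatial
sources over ``V`` samples through its own random mixing matrix.  Across
subjects, source n of the K subjects forms a source component vector whose
correlation structure is planted directly: a Gaussian copula with a block
covariance (``rho_in`` within each planted subject block, ``rho_out``
between all other pairs) is pushed through generalized-Gaussian marginals,
yielding correlated-but-non-Gaussian sources.  The background correlation
``rho_out`` plays the role of the common network template every subject
partially expresses (what makes reference-constrained decomposition
feasible); the block excess ``rho_in - rho_out`` is the homogeneous-subgroup
signal the pipeline is meant to find.

References are the across-subject mean source maps plus Gaussian noise
calibrated so that ``corr(reference, mean map) ~= reference_fidelity``.

The marginal transform attenuates the copula correlation slightly, so the
generator *measures* realized correlations (reported in ``GroundTruth``)
rather than promising the targets exactly.

All randomness flows from one seed through named substreams (sources,
mixing, reference noise), so fixtures are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .constrained import ReferenceSet
from .ica import SubjectData, whiten

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate",
    "end_to_end_fixture",
    "limitation_fixture",
    "PRESETS",
]

# default generalized-Gaussian shape cycle: mixed super- and sub-Gaussian,
# all clearly non-Gaussian (|excess kurtosis| > 0.5)
_SHAPE_CYCLE = (0.5, 1.0, 4.0, 0.7, 10.0, 1.5, 3.0, 0.6)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic multi-subject dataset."""

    K: int = 40
    N: int = 10
    V: int = 20000
    n_subgrouped_components: int = 3
    blocks: Sequence[tuple[Sequence[int], float]] = ((tuple(range(10)), 0.8),)
    rho_out: float = 0.2
    source_shape: Optional[Sequence[float]] = None
    mixing_condition: float = 10.0
    reference_fidelity: float = 0.9
    seed: int = 0

    def shapes(self) -> np.ndarray:
        if self.source_shape is not None:
            return np.broadcast_to(np.asarray(self.source_shape, float),
                                   (self.N,)).copy()
        return np.array([_SHAPE_CYCLE[n % len(_SHAPE_CYCLE)]
                         for n in range(self.N)])

    def validate(self) -> None:
        if self.K < 2 or self.N < 2 or self.V <= self.N:
            raise ValueError("need K >= 2, N >= 2 and V > N")
        if not 0.0 < self.reference_fidelity <= 1.0:
            raise ValueError("reference_fidelity must lie in (0, 1]")
        if self.n_subgrouped_components > self.N:
            raise ValueError("more subgrouped components than components")
        used = set()
        for idx, rho_in in self.blocks:
            idx = set(int(i) for i in idx)
            if idx & used:
                raise ValueError("planted blocks must be disjoint")
            if not idx <= set(range(self.K)):
                raise ValueError("block subject index out of range")
            used |= idx
            if not self.rho_out <= rho_in <= 1.0 or not 0.0 <= self.rho_out:
                raise ValueError("need 0 <= rho_out <= rho_in <= 1")
        # the copula covariance must be positive definite
        for n in range(self.N):
            try:
                np.linalg.cholesky(self._copula_cov(n))
            except np.linalg.LinAlgError as e:
                raise ValueError(
                    "rho settings give a non-positive-definite covariance") from e

    def _copula_cov(self, n: int) -> np.ndarray:
        C = np.full((self.K, self.K), self.rho_out)
        np.fill_diagonal(C, 1.0)
        if n < self.n_subgrouped_components:
            for idx, rho_in in self.blocks:
                idx = np.fromiter(idx, dtype=int)
                C[np.ix_(idx, idx)] = rho_in
                C[idx, idx] = 1.0
        return C

    def block_labels(self) -> np.ndarray:
        """Planted subject labels: block id for members, -1 for the rest."""
        lab = np.full(self.K, -1, dtype=int)
        for b, (idx, _) in enumerate(self.blocks):
            lab[np.fromiter(idx, dtype=int)] = b
        return lab


@dataclass
class GroundTruth:
    """True mixing, sources, planted labels and realized correlations."""

    mixing: list[np.ndarray]
    sources: list[np.ndarray]
    block_labels: np.ndarray
    component_blocked: np.ndarray
    references: np.ndarray
    realized_block_corr: dict[int, float] = field(default_factory=dict)
    realized_background_corr: float = 0.0

    def scv(self, n: int) -> np.ndarray:
        """K x V stack of true source n across subjects."""
        return np.vstack([S[n] for S in self.sources])


def _bounded_condition_mixing(N: int, cond: float,
                              rng: np.random.Generator) -> np.ndarray:
    u, _ = np.linalg.qr(rng.standard_normal((N, N)))
    v, _ = np.linalg.qr(rng.standard_normal((N, N)))
    s = np.logspace(0.0, -np.log10(cond), N)
    return u * s @ v.T


def generate(config: SimulationConfig
             ) -> tuple[list[SubjectData], ReferenceSet, GroundTruth]:
    """Draw one multi-subject dataset under the configured study conditions.

    Returns whitened per-subject data (ready for the constrained
    decomposition), the noisy reference set, and the ground truth.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_src, rng_mix, rng_ref = (np.random.default_rng(c)
                                 for c in ss.spawn(3))
    K, N, V = config.K, config.N, config.V
    shapes = config.shapes()

    sources = np.empty((K, N, V))
    for n in range(N):
        L = np.linalg.cholesky(config._copula_cov(n))
        Z = L @ rng_src.standard_normal((K, V))
        U = stats.norm.cdf(Z)
        S = stats.gennorm.ppf(np.clip(U, 1e-12, 1 - 1e-12), shapes[n])
        S = (S - S.mean(axis=1, keepdims=True)) / S.std(axis=1, ddof=1,
                                                        keepdims=True)
        sources[:, n, :] = S

    mixing = [_bounded_condition_mixing(N, config.mixing_condition, rng_mix)
              for _ in range(K)]
    subjects = []
    for k in range(K):
        X = mixing[k] @ sources[k]
        subjects.append(whiten(X, N, subject_id=f"subject{k:03d}"))

    # references: standardized mean maps plus calibrated Gaussian noise
    mean_maps = sources.mean(axis=0)
    mean_maps = (mean_maps - mean_maps.mean(axis=1, keepdims=True))
    mean_maps /= mean_maps.std(axis=1, ddof=1, keepdims=True)
    f = config.reference_fidelity
    eta = np.sqrt(1.0 / f**2 - 1.0)
    noise = rng_ref.standard_normal((N, V)) if eta > 0 else np.zeros((N, V))
    R = mean_maps + eta * noise
    refs = ReferenceSet(R, labels=[f"net{n}" for n in range(N)])

    labels = config.block_labels()
    blocked = np.array([n < config.n_subgrouped_components for n in range(N)])
    gt = GroundTruth(mixing=mixing, sources=[sources[k] for k in range(K)],
                     block_labels=labels, component_blocked=blocked,
                     references=refs.R.copy())
    # realized correlations, measured on the first blocked component (if any)
    bg_vals = []
    for n in range(min(N, config.n_subgrouped_components or 1)):
        C = np.corrcoef(sources[:, n, :])
        outside = labels < 0
        if outside.sum() >= 2:
            sub = C[np.ix_(outside, outside)]
            bg_vals.append(sub[np.triu_indices(outside.sum(), k=1)].mean())
        for b, (idx, _) in enumerate(config.blocks):
            idx = np.fromiter(idx, dtype=int)
            if idx.size >= 2 and n < config.n_subgrouped_components:
                sub = C[np.ix_(idx, idx)]
                val = sub[np.triu_indices(idx.size, k=1)].mean()
                gt.realized_block_corr[b] = float(
                    np.mean([gt.realized_block_corr.get(b, val), val]))
    gt.realized_background_corr = float(np.mean(bg_vals)) if bg_vals else 0.0
    return subjects, refs, gt


PRESETS: dict[str, SimulationConfig] = {
    "tiny": SimulationConfig(K=8, N=4, V=5000, n_subgrouped_components=2,
                             blocks=((tuple(range(3)), 0.8),), rho_out=0.2),
    "standard": SimulationConfig(K=40, N=10, V=20000,
                                 n_subgrouped_components=3,
                                 blocks=((tuple(range(10)), 0.8),),
                                 rho_out=0.2),
    "stress": SimulationConfig(K=200, N=20, V=20000,
                               n_subgrouped_components=4,
                               blocks=((tuple(range(50)), 0.8),),
                               rho_out=0.2),
}


def end_to_end_fixture(preset: str, seed: int = 0,
                       out_dir: str | Path | None = None):
    """Materialize a named preset, optionally writing it to disk.

    Writes per-subject whitened matrices, references and ground-truth labels
    in the pipeline's native formats (.npy matrices + JSON sidecar);
    deterministic for a given seed.  Returns (subjects, refs, ground_truth).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset '{preset}' (choose from {sorted(PRESETS)})")
    cfg = SimulationConfig(**{**PRESETS[preset].__dict__, "seed": seed})
    subjects, refs, gt = generate(cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sub in subjects:
            np.save(out / f"{sub.subject_id}.npy", sub.X)
        np.save(out / "references.npy", refs.R)
        meta = {
            "preset": preset, "seed": seed, "K": cfg.K, "N": cfg.N,
            "V": cfg.V, "block_labels": gt.block_labels.tolist(),
            "component_blocked": gt.component_blocked.tolist(),
            "reference_labels": refs.labels,
            "realized_block_corr": gt.realized_block_corr,
            "realized_background_corr": gt.realized_background_corr,
        }
        (out / "ground_truth.json").write_text(json.dumps(meta, indent=2))
    return subjects, refs, gt


def limitation_fixture(K: int, seed: int = 0, block_fractions=(0.25, 0.15),
                       block_rhos=(0.7, 0.3), noise_sd: float = 0.06,
                       block_sizes=None) -> tuple[np.ndarray, np.ndarray]:
    """Noisy planted-block correlation matrix for the large-K limitation demo.

    Plants correlated subject blocks over symmetrized Gaussian background
    noise and returns (C, planted_labels).  The smallest Gershgorin radius
    grows linearly with K (every off-diagonal noise entry contributes its
    absolute value), which is the documented weakness of the disc-count rule
    on large cohorts:

    - with ``block_fractions`` (default), block eigenvalues grow with K as
      well, so the detected count stays at best constant — it can never
      benefit from more subjects;
    - with ``block_sizes`` (fixed absolute subgroup sizes), block
      eigenvalues stay put while ``R_min + 1`` keeps climbing, so blocks
      drop below the detection threshold one after the other as K grows —
      the undercount in its starkest form.
    """
    rng = np.random.default_rng(seed)
    C = np.eye(K)
    labels = np.full(K, -1, dtype=int)
    start = 0
    if block_sizes is not None:
        sizes = list(block_sizes)
    else:
        sizes = [max(2, int(round(f * K))) for f in block_fractions]
    for b, (g, rho) in enumerate(zip(sizes, block_rhos)):
        idx = np.arange(start, min(start + g, K))
        C[np.ix_(idx, idx)] = rho
        labels[idx] = b
        start += g
    np.fill_diagonal(C, 1.0)
    E = rng.normal(0.0, noise_sd, (K, K))
    E = (E + E.T) / 2.0
    np.fill_diagonal(E, 0.0)
    return np.clip(C + E, -1.0, 1.0), labels
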