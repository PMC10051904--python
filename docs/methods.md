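# Methods

This note documents the models, numerical choices and limitations behind
`fsig`: a pipeline that aligns per-subject ICA decompositions of fMRI
activity maps to shared network templates and detects homogeneous subject
subgroups from the cross-subject covariance of each aligned component.

## 1. Entropy bound estimation

### Model

A source estimate `y` (zero mean, unit variance) has entropy bounded above,
for every measuring function `G_m`, by the entropy `O_m(t)` of the
maximum-entropy density with `E[y]=0`, `E[y^2]=1`, `E[G_m(y)] = t`. The
negentropy estimate is `max_m [½log(2πe) − O_m(E[G_m(y)])]`: the tightest
bound wins, and the winning index `m*` also selects the nonlinearity used in
the gradient. Four fixed measuring functions are used — `x⁴` and
`|x|/(1+|x|)` (even; tail-weight sensitive, covering sub- and super-Gaussian
sources) and `x|x|/(10+|x|)` and `x/(1+x²)` (odd; skew sensitive).

### Numerical construction of the bound tables

The bounds have no closed form. At build time, for each `G_m`, the
exponential-family maximum-entropy problem
`p(y) ∝ exp(c₁y + c₂y² + c₃G_m(y))` is solved on a 512-point grid of target
moments `t`: Newton iteration on the moment-matching conditions, whose
Jacobian is the covariance matrix of the basis functions under the current
density, with residual-norm backtracking and warm-started continuation
outward from the Gaussian point. Integrals use trapezoidal quadrature on a
4001-point grid over [−10, 10]; this truncation regularizes the otherwise
non-normalizable branch of the `x⁴` problem and biases entropies by an
amount far below the estimator's Monte-Carlo noise. For the even functions
`c₁ = 0` by symmetry (a one-fewer-parameter solve); for the odd functions
the bound is an even function of `t`, so only `t ≥ 0` is tabulated and
queries use `|t|` — which makes the negentropy estimate exactly invariant
under `y → −y`.

The attainable moment range per function is computed by deterministic
quadrature over a family of realistic unit-variance densities (generalized
Gaussians with shape 0.42–10, symmetric bimodal Gaussian mixtures
approaching a two-point law, and both skews of standardized gammas for the
odd functions). Moments outside the tabulated support are clamped (with a
warning), which zeroes that function's gradient contribution there.
Non-convergent grid points are excluded from the interpolation support with
a warning; in practice all 2048 points converge.

Bounds and derivatives are interpolated with monotone cubic (PCHIP) splines;
the derivative is the exact derivative of the interpolant. Tables are cached
as a versioned `.npz` in the user cache directory and rebuilt automatically
when absent (about two seconds at the default 512-point resolution). The
public negentropy value is clipped at zero (an entropy *upper* bound cannot
produce negative negentropy; interpolation noise of order 1e−6 otherwise
could); the optimizer uses the unclipped value internally so its gradient
stays exact.

Checks worth knowing about: at the Gaussian moment the tabulated bound
equals ½log(2πe) to better than 1e−2 nats with derivative ≈ 0, and a
unit-variance Laplace sample (true negentropy ≈ 0.072 nats) scores above
0.05 — the bound family is tight but not exact for any single density.

## 2. Decoupled ICA-EBM

The mutual-information ICA cost separates into per-row problems
`J_n(w_n) = −negentropy(ŷ_n) − log|d_nᵀw_n|`, with `d_n` the unit vector
orthogonal to all rows of `W` except row n (computed from a QR null space;
sign fixed so `d_nᵀw_n > 0`). No orthogonality is imposed on `W`.

Numerical conventions:

- `ŷ_n` is standardized inside the cost (zero mean, unit variance with
  `ddof=1`, matching the whitening convention `XXᵀ/(V−1) = I`). The
  analytic gradient therefore carries the standardization chain-rule terms;
  on whitened data with unit-norm rows these reduce to the classic EBM
  update terms plus a radial component that row renormalization removes.
  The gradient is verified against central finite differences of the cost
  (relative error < 1e−4; observed ~1e−10).
- Optimization is cyclic row-wise gradient descent with an Armijo
  backtracking line search (halving; sufficient-decrease constant 1e−4 on
  the tangential gradient norm; step memory doubled on success). Candidate
  rows are renormalized to the unit sphere before evaluation, so accepted
  steps never increase the row cost and the per-row cost trace is recorded
  as evidence.
- Convergence: `max_n (1 − |w_n_newᵀw_n_old|) < tol` (default 1e−6) or 512
  sweeps, then a warning. Sign convention: each source is flipped so its
  skewness (fallback: largest-magnitude sample) is positive.
- Initialization is a seeded random orthogonal matrix. Row-wise descent can
  stall with one sub-Gaussian source pair left mixed (about 2 of 10 seeds
  at N=4); the `n_init` option reruns from fresh seeds and keeps the lowest
  total decoupled cost. The default is a single initialization, which is
  what the run-to-run consistency diagnostics (cross-ISI) are designed to
  probe.

## 3. Constrained EBM (c-EBM)

Each constrained row adds the inequality `h_n = θ_n − |corr(r_n, ŷ_n)| ≤ 0`
via the augmented Lagrangian `(max(0, γh_n + μ_n)² − μ_n²)/(2γ)`, with
`μ_n ← max(0, γh_n + μ_n)` once per sweep (slack variable eliminated
analytically). Defaults: `θ = 0.3` for all constrained components — low on
purpose, preserving the inter-subject variability the subgroup stage needs —
and `γ = 3`, fixed with no schedule; the penalty only has to dominate near
the constraint boundary, and the contract tests exercise θ from 0 to 0.9.
`μ` starts at 0 (unconstrained start, standard practice).

Reference k constrains component k, so constrained components come out in
reference order across all subjects and no post-hoc matching is needed.
Constrained rows are initialized at the projection of their reference onto
the whitened data space (random orthogonal completion for the rest): with a
fully random start, row-wise descent can converge to a permutation in which
a different row holds the referenced source, leaving the constrained row
pinned at the constraint boundary instead of snapping onto the source.
Because the similarity uses |corr|, the constraint is exactly blind to the
sign of the reference; final constrained components are sign-aligned to
their reference, unconstrained ones follow the skewness convention.

With `θ = 0` the penalty term is identically zero (h ≤ 0 and μ stays 0), so
a c-EBM fit from a given initialization reproduces the unconstrained fit
from the same initialization exactly — a useful regression anchor.

Subjects are fitted independently (per-subject seeds); results are
contractually independent of processing order.

## 4. Subgroup identification

**SCV covariance.** Component n of all K subjects forms `Y_n` (K × V, rows
standardized, sign-aligned to the references before stacking — without the
alignment the |corr| constraint can plant artificial negative blocks).
`C_n = Y_nY_nᵀ/(V−1)`, renormalized to exact unit diagonal and symmetrized.

**Step I — SCV clustering.** k-means (20 seeded restarts) on the vectorized
upper triangles of the `C_n`; for every candidate cluster count I, each
cluster's mean matrix `C̄` is scored by the modularity of its detector
partition, and the (I, cluster) pair with the highest modularity is kept.
Averaging correlation matrices preserves the unit diagonal, so the detector
threshold below stays well defined on `C̄`.

**Step II — Gershgorin detector.** Radii `R_i = Σ_{j≠i}|ρ_ij|`,
`R_min = min_i R_i`; the subgroup count B is the number of eigenvalues
strictly greater than `R_min + 1`, with a 1e−9 absolute guard so unit
eigenvalues of uncorrelated subjects (exactly on the boundary) are not
miscounted by floating-point noise. Membership: the default assignment runs
(B+1)-means jointly on the K × B matrix of outlying-eigenvector loadings —
subjects of one block have (near-)identical rows, unassigned subjects sit
near the origin, and the geometry is invariant to rotations within
degenerate eigenspaces (two equal-strength blocks share an eigenvalue, and
the eigensolver's basis for that subspace is arbitrary; any per-eigenvector
rule is unstable there). The cluster whose centroid is nearest the origin
becomes "rest" (label −1). A per-eigenvector alternative (independent
2-means on absolute loadings, overlaps resolved by the larger loading) is
available as `assign="per_eigenvector"`.

**Modularity.** No canonical definition exists for weighted correlation
matrices; Newman–Girvan modularity on edge weights `|ρ_ij|` (diagonal
excluded) is used, with every subgroup one community and the whole "rest"
group a single community. An all-zero off-diagonal returns Q = 0. The
implementation is direct (closed-form on the matrix); the graph-library
route is kept as an independent cross-check in the tests.

**Known limitation — large cohorts.** `R_min` accumulates one |ρ| per
subject pair, so it grows linearly in K under any fixed level of background
correlation noise. Two regimes, both demonstrated (not fixed) by the test
suite: with block *fractions* fixed, block eigenvalues grow linearly too and
the detected count stays at best constant as K grows from 20 to 400; with
block *sizes* fixed, block eigenvalues stay put while the threshold climbs,
and planted subgroups vanish from the count (B: 2 → 0 between K=20 and
K=400 on the default demo fixtures). Practical consequence: on large
cohorts the rule undercounts; clustering SCVs first (Step I) mitigates this
by sharpening the blocks in `C̄` but does not remove the scaling.

## 5. Validation statistics

Voxelwise two-sample t-tests use the pooled-variance (Student) form — the
conventional choice for voxelwise contrasts; zero-pooled-variance voxels get
t = 0 and are counted with a warning. FDR control is Benjamini–Hochberg per
component map at q = 0.05 by default. The map summary `t_q` is the signed t
at the largest-|t| FDR-significant voxel (option: mean |t| over significant
voxels); the global difference map is `Σ_q (|t_q|/Σ_l|t_l|) T_q`, with the
absolute value also in the denominator so weights are nonnegative and sum to
one. Because the similarity constraint is sign-blind, t-map signs are
meaningful only after the reference sign alignment of Section 4. A generic
covariate comparison (per-column two-sample t-tests with mean imputation of
missing entries) supports behavioral validation of detected subgroups.

## 6. Model-order diagnostics

The joint ISI of a global matrix G is
`[Σ_n(Σ_m|g_nm|/max_p|g_np| − 1) + Σ_m(Σ_n|g_nm|/max_p|g_pm| − 1)] /
[2N(N−1)]` — zero exactly on signed scaled permutations, one for the fully
mixed case. The second term is normalized by column maxima; a row-max
variant is available behind an option but is not invariant under column
scaling and is not the default. Note the index is invariant under
permutations, sign flips and a common rescaling, but not under independent
row-and-column rescaling of a non-permutation matrix.

Cross-ISI between runs i and j is `ISI(W_j A_i)` with `A_i = W_i⁻¹`: run i's
mixing composed with run j's demixing, which is a signed scaled permutation
exactly when the two runs found the same sources. The per-run score averages
over partners; the order-selection scan whitens to each candidate order,
runs R seeded decompositions, and reports the per-order cross-ISI
distribution. The shortlist flags orders whose median is within 0.02 of the
best and whose IQR is at most twice the best IQR among those; the "best run"
is the one with the smallest cross-ISI inside the chosen order. The final
choice is deliberately left to the caller — spatial plausibility and
spectral content of the components matter as much as consistency.

Template generation uses the standard two-level scheme: per-subject PCA to
1.5× the model order (capped by subject rank), concatenation, group PCA to
the model order, ICA-EBM on the group-reduced data (spatial maps live
directly in voxel space), and least-squares back-projection for per-subject
time courses. RSN filtering ranks components by the ratio of spectral power
below 0.10 Hz to power above 0.15 Hz (both cutoffs configurable; a
physiologically driven BOLD component concentrates power at low
frequencies), with an optional peak-location inclusion mask and an explicit
override list, since final template selection in practice involves visual
inspection.

## 7. Synthetic study conditions

The generator plants the cross-subject structure directly in the sources:
for each component, a Gaussian copula with block covariance (`rho_in` within
planted subject blocks, `rho_out` between all other pairs) is pushed through
generalized-Gaussian marginals (default shape cycle mixing clearly super-
and sub-Gaussian laws, |excess kurtosis| > 0.5 throughout — the ICA
identifiability requirement). The background correlation `rho_out` is not a
nuisance: it models the common network template every subject partially
expresses, and it is what makes the reference constraint feasible — with
`rho_out = 0.2`, a subject's map correlates ≈ 0.35–0.45 with the group mean,
comfortably above θ = 0.3. The marginal transform attenuates the copula
correlation (target 0.8 realizes ≈ 0.76–0.78, shape-dependent), so the
generator measures and reports realized correlations instead of promising
the targets.

Mixing matrices are random with condition number bounded by 10 (singular
values log-spaced). References are the standardized across-subject mean
source maps plus Gaussian noise calibrated so corr(reference, mean map)
≈ `reference_fidelity` (default 0.9; exact at fidelity 1). All randomness
derives from one seed through named substreams (sources, mixing, reference
noise), making fixtures byte-reproducible.

Presets: `tiny` (K=8, N=4, V=5000; block of 3 at 0.8), `standard` (K=40,
N=10, V=20000; one block of 10 at 0.8 carried by 3 of 10 components),
`stress` (K=200, N=20, V=20000; block of 50). The standard preset is the
end-to-end benchmark: constrained decomposition of all 40 subjects followed
by the subgroup stage recovers the planted membership with adjusted Rand
≥ 0.8 (observed: 1.0) in under a minute on one CPU.

What the generator does *not* emulate: spatial smoothness and anatomical
layout of real activation maps, hemodynamic time-course structure, scanner
artifacts and motion, and site effects. Passing tests therefore establish
the correctness and calibration of the algorithms under the stated
statistical model, not performance on real fMRI; on real data the realized
reference fidelity, the noise level of the SCV covariances, and the
adequacy of the model order are all empirical questions the diagnostics of
Sections 5–6 are meant to inform.

## 8. Problem sizes used by the test suite and acceptance script

Source-recovery checks use N=4, V=20000 over 10 seeds; the constrained-fit
contract uses N=4, V=5000; the end-to-end benchmark is the standard preset
(K=40, N=10, V=20000); detector oracles use K ≤ 12 noiseless and K=12 noisy
matrices over 20 seeds; the large-cohort demonstration uses K ∈ {20, 100,
400} correlation fixtures. These sizes keep the full suite and the
acceptance script each within a few minutes on a single CPU while leaving
every statistical margin wide (the observed end-to-end adjusted Rand is 1.0
against an acceptance floor of 0.8).
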