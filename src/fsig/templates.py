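"""Group-level reference (template) generation.

Resting-state-network templates for the constrained decomposition are
extracted from an independent multi-subject dataset with the standard
two-level group ICA scheme: a first-level PCA reduces every subject's
time-by-voxel data, the reductions are concatenated along the (reduced)
time dimension, a second-level PCA whitens the concatenation to the chosen
model order, and ICA-EBM on the group-reduced data yields spatial maps that
live directly in voxel space.

Component time courses are recovered per subject by least-squares
back-projection and support the physiological-plausibility filter: a
BOLD-driven network concentrates spectral power at low frequencies, so the
ratio of power below ``low_cut`` to power above ``high_cut`` ranks
components, complemented by an optional peak-location mask and a manual
override list (final template selection is partly a judgment call; the
quantitative criteria keep it scriptable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .entropy import EntropyBoundTable, default_table
from .ica import SubjectData, ica_ebm_fit, whiten

__all__ = [
    "GroupDecomposition",
    "RSNSelection",
    "group_ica_ebm",
    "power_ratio",
    "select_rsns",
]


@dataclass
class GroupDecomposition:
    """Two-level PCA + ICA-EBM group decomposition."""

    group_maps: np.ndarray
    timecourses: list[np.ndarray]
    subject_reductions: list[np.ndarray]
    model_order: int
    run_seed: Optional[int]
    converged: bool = True


@dataclass
class RSNSelection:
    """Components retained as resting-state-network templates."""

    selected_indices: np.ndarray
    power_ratio: np.ndarray
    labels: list[str] = field(default_factory=list)


def group_ica_ebm(subjects: Sequence[np.ndarray], model_order: int,
                  table: EntropyBoundTable | None = None,
                  seed: int | None = None, first_level_factor: float = 1.5,
                  max_iterations: int = 512, tolerance: float = 1e-6,
                  n_init: int = 1) -> GroupDecomposition:
    """Two-level PCA + ICA-EBM on a multi-subject dataset.

    ``subjects`` are raw time-by-voxel matrices sharing the voxel grid.  The
    first-level PCA order is ``first_level_factor * model_order`` capped by
    each subject's rank; spatial maps are returned in original voxel space
    (rows of the group source matrix), with per-subject time courses from
    least-squares back-projection.
    """
    subjects = [np.asarray(s, dtype=float) for s in subjects]
    if len(subjects) < 2:
        raise ValueError("group ICA needs at least two subjects")
    V = subjects[0].shape[1]
    if any(s.shape[1] != V for s in subjects):
        raise ValueError("subjects must share the voxel grid")
    if table is None:
        table = default_table()
    level1 = int(np.ceil(first_level_factor * model_order))
    reduced = []
    transforms = []
    for k, raw in enumerate(subjects):
        order_k = min(level1, min(raw.shape))
        sub = whiten(raw, order_k, subject_id=f"subject{k}")
        reduced.append(sub.X)
        transforms.append(sub.whitening_transform)
    concat = np.vstack(reduced)
    if model_order > min(concat.shape):
        raise ValueError(
            f"model order {model_order} exceeds concatenated rank {min(concat.shape)}")
    group = whiten(concat, model_order, subject_id="group")
    state = ica_ebm_fit(group, table, seed=seed,
                        max_iterations=max_iterations, tolerance=tolerance,
                        n_init=n_init)
    maps = state.Y
    pinv_maps = np.linalg.pinv(maps)
    tcs = []
    for raw in subjects:
        centered = raw - raw.mean(axis=1, keepdims=True)
        tcs.append(centered @ pinv_maps)
    return GroupDecomposition(group_maps=maps, timecourses=tcs,
                              subject_reductions=transforms,
                              model_order=model_order, run_seed=seed,
                              converged=state.converged)


def power_ratio(timecourse: np.ndarray, sampling_period: float,
                low_cut: float = 0.10, high_cut: float = 0.15) -> float:
    """Low-to-high-frequency spectral power ratio of a component time course.

    Power in (0, ``low_cut``] divided by power in [``high_cut``, Nyquist];
    +inf when the high band carries no power.  BOLD-plausible components
    score high.
    """
    x = np.asarray(timecourse, dtype=float).ravel()
    if x.size < 16:
        raise ValueError("time course too short (need >= 16 samples)")
    nyquist = 0.5 / sampling_period
    if not 0 < low_cut < high_cut < nyquist:
        raise ValueError("need 0 < low_cut < high_cut < Nyquist")
    f, pxx = signal.periodogram(x, fs=1.0 / sampling_period)
    low = float(pxx[(f > 0) & (f <= low_cut)].sum())
    high = float(pxx[f >= high_cut].sum())
    total = float(pxx[f > 0].sum())
    # high band carrying only numerical dust counts as empty
    if high <= 1e-12 * max(total, 1e-300):
        return np.inf
    return low / high


def select_rsns(decomp: GroupDecomposition, sampling_period: float,
                min_power_ratio: float = 0.0,
                low_cut: float = 0.10, high_cut: float = 0.15,
                include_mask: np.ndarray | None = None,
                override: Sequence[int] | None = None,
                labels: Sequence[str] | None = None) -> RSNSelection:
    """Filter group components into resting-state-network templates.

    Keeps components whose subject-averaged power ratio reaches
    ``min_power_ratio`` and (optionally) whose peak-|activation| voxel lies
    inside ``include_mask``; an explicit ``override`` index list replaces the
    automatic choice.  An empty selection is returned with a warning.
    """
    n_comp = decomp.group_maps.shape[0]
    ratios = np.empty(n_comp)
    for n in range(n_comp):
        vals = [power_ratio(tc[:, n], sampling_period, low_cut, high_cut)
                for tc in decomp.timecourses]
        finite = [v for v in vals if np.isfinite(v)]
        ratios[n] = np.mean(finite) if finite else np.inf
    if override is not None:
        idx = np.asarray(sorted(override), dtype=int)
    else:
        keep = ratios >= min_power_ratio
        if include_mask is not None:
            include_mask = np.asarray(include_mask, dtype=bool).ravel()
            peaks = np.argmax(np.abs(decomp.group_maps), axis=1)
            keep &= include_mask[peaks]
        idx = np.flatnonzero(keep)
    if idx.size == 0:
        warnings.warn("no component passed the RSN selection criteria",
                      RuntimeWarning)
    lab = list(labels) if labels is not None else [f"RSN{i}" for i in idx]
    return RSNSelection(selected_indices=idx, power_ratio=ratios, labels=lab)
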