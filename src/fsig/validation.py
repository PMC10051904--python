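"""Statistical comparison of identified subgroups.

Voxelwise two-sample t-maps (pooled variance) contrast the spatial activation
of a functional-network component between a subgroup and the remaining
subjects; Benjamini-Hochberg FDR correction controls the expected fraction
of falsely flagged voxels per map.  When several components discriminate the
same partition, the global difference map (GDM) summarizes them as the
|t|-weighted average of their t-maps,

    T_GDM = sum_q ( |t_q| / sum_l |t_l| ) * T_q ,

with ``t_q`` the summary t-statistic of map q (peak |t| over its significant
voxels by default), so the weights are nonnegative and sum to one.

A generic covariate comparison (two-sample tests over a subject-by-score
table) supports validating subgroups against behavioral measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TMapResult",
    "GDMResult",
    "two_sample_tmap",
    "fdr_correct",
    "global_difference_map",
    "compare_covariates",
]


@dataclass
class TMapResult:
    """Voxelwise two-sample t-test of one component between two groups."""

    component_index: int
    t_values: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    significant_mask: np.ndarray
    peak_t: float
    group_sizes: tuple[int, int]
    n_zero_variance: int = 0


@dataclass
class GDMResult:
    """|t|-weighted summary of several discriminating t-maps."""

    weights: np.ndarray
    map: np.ndarray
    contributing_components: list[int]


def two_sample_tmap(maps_g1: np.ndarray, maps_g2: np.ndarray,
                    component_index: int = 0, alpha: float = 0.05,
                    summary: str = "peak") -> TMapResult:
    """Pooled-variance two-sample t-test at every voxel.

    ``maps_g1`` (n1 x V) and ``maps_g2`` (n2 x V) hold the per-subject
    activation maps of the two groups.  Voxels with zero pooled variance get
    t = 0 (counted in ``n_zero_variance`` with a warning).  The summary
    scalar ``peak_t`` is the signed t at the largest-|t| voxel inside the
    FDR-significant mask (``summary="peak"``), or the mean |t| over the
    significant voxels (``summary="mean"``); 0 if nothing is significant.
    """
    g1 = np.atleast_2d(np.asarray(maps_g1, dtype=float))
    g2 = np.atleast_2d(np.asarray(maps_g2, dtype=float))
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two subjects")
    if g1.shape[1] != g2.shape[1]:
        raise ValueError("groups must share the voxel grid")
    t, p = stats.ttest_ind(g1, g2, axis=0, equal_var=True)
    bad = ~np.isfinite(t)
    n_zero = int(bad.sum())
    if n_zero:
        warnings.warn(f"{n_zero} voxel(s) with zero pooled variance; t set to 0",
                      RuntimeWarning)
        t = np.where(bad, 0.0, t)
        p = np.where(bad, 1.0, p)
    q, mask = fdr_correct(p, alpha)
    if mask.any():
        if summary == "peak":
            idx = np.flatnonzero(mask)[np.argmax(np.abs(t[mask]))]
            peak = float(t[idx])
        elif summary == "mean":
            peak = float(np.mean(np.abs(t[mask])))
        else:
            raise ValueError("summary must be 'peak' or 'mean'")
    else:
        peak = 0.0
    return TMapResult(component_index=component_index, t_values=t, p_values=p,
                      q_values=q, significant_mask=mask, peak_t=peak,
                      group_sizes=(n1, n2), n_zero_variance=n_zero)


def fdr_correct(p_values: np.ndarray, q: float = 0.05
                ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction.

    Returns ``(q_values, significant_mask)`` with adjusted q-values
    monotone over the sorted p-values and the rejection mask at level ``q``.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("FDR level q must lie in (0, 1)")
    reject, q_values, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_values, reject


def global_difference_map(tmaps: Sequence[TMapResult]) -> GDMResult:
    """|t|-weighted average of the t-maps of discriminating components.

    Weights are ``|t_q| / sum_l |t_l|`` over the supplied maps; every
    peak-t must not all be zero.
    """
    tmaps = list(tmaps)
    if not tmaps:
        raise ValueError("need at least one t-map")
    peaks = np.array([tm.peak_t for tm in tmaps], dtype=float)
    denom = np.sum(np.abs(peaks))
    if denom == 0:
        raise ValueError("all peak t-statistics are zero; GDM undefined")
    w = np.abs(peaks) / denom
    gdm = np.zeros_like(tmaps[0].t_values, dtype=float)
    for wi, tm in zip(w, tmaps):
        gdm += wi * tm.t_values
    return GDMResult(weights=w, map=gdm,
                     contributing_components=[tm.component_index for tm in tmaps])


def compare_covariates(scores: pd.DataFrame, labels: Sequence,
                       group_a=0, group_b=-1) -> pd.DataFrame:
    """Two-sample t-tests of each score column between two subject groups.

    ``scores`` is subject-by-score; ``labels`` assigns each subject a group
    id (e.g. subgroup membership, -1 for the remainder).  Missing scores are
    mean-imputed per column.  Returns a tidy table (score, t, p, n_a, n_b).
    """
    labels = np.asarray(list(labels))
    if len(labels) != len(scores):
        raise ValueError("labels must match the number of subjects")
    filled = scores.apply(lambda c: c.fillna(c.mean()))
    a = filled[labels == group_a]
    b = filled[labels == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two subjects")
    rows = []
    for col in filled.columns:
        t, p = stats.ttest_ind(a[col], b[col], equal_var=True)
        rows.append({"score": col, "t": float(t), "p": float(p),
                     "n_a": len(a), "n_b": len(b)})
    return pd.DataFrame(rows)
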