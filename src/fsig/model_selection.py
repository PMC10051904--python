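"""Run-to-run consistency metrics (ISI, cross-ISI) and model-order selection.

The joint inter-symbol-interference (ISI) index scores a global
mixing-demixing product ``G = A W``: it is 0 exactly when ``G`` is a signed,
scaled permutation (perfect separation up to the intrinsic ICA ambiguities)
and 1 in the fully mixed case.  Cross-ISI compares independent ICA runs —
``ISI(A_i W_j)`` measures how consistent run j's demixing is with run i's
mixing — and its per-run average is a practical, ground-truth-free proxy for
the stability of a given model order: orders that match the data yield runs
that keep finding the same sources, hence small cross-ISI with small spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ica import SubjectData, ica_ebm_fit, whiten
from .entropy import EntropyBoundTable, default_table

__all__ = ["isi", "cross_isi", "order_selection", "ConsistencyResult"]


def isi(G: np.ndarray, second_term: str = "col_max") -> float:
    """Normalized joint ISI of a square matrix, in [0, 1].

    ``second_term="col_max"`` (default) is the standard form whose column sums
    are normalized by column maxima, invariant under row/column rescaling and
    permutation.  ``"row_max"`` normalizes the column-sum term by row maxima
    instead (a printed variant that is not column-scale invariant).
    """
    G = np.abs(np.asarray(G, dtype=float))
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("G must be square")
    N = G.shape[0]
    row_max = G.max(axis=1)
    col_max = G.max(axis=0)
    if np.any(row_max == 0) or np.any(col_max == 0):
        raise ValueError("ISI undefined: G has an all-zero row or column")
    term_rows = float(np.sum(G / row_max[:, None]) - N)
    if second_term == "col_max":
        term_cols = float(np.sum(G / col_max[None, :]) - N)
    elif second_term == "row_max":
        term_cols = float(np.sum(G.sum(axis=0) / row_max) - N)
    else:
        raise ValueError("second_term must be 'col_max' or 'row_max'")
    return (term_rows + term_cols) / (2.0 * N * (N - 1))


def cross_isi(runs: list[np.ndarray]) -> np.ndarray:
    """Per-run average cross-ISI over a list of demixing matrices.

    ``ISI_c[i] = mean_{j != i} ISI(W_j @ inv(W_i))``: run i's mixing matrix
    composed with run j's demixing gives the identity-up-to-permutation
    global matrix exactly when the two runs found the same sources.  Small
    values mark runs consistent with the others.
    """
    R = len(runs)
    if R < 2:
        raise ValueError("need at least two runs")
    N = runs[0].shape[0]
    inv = []
    for i, W in enumerate(runs):
        if W.shape != (N, N):
            raise ValueError("all runs must share the same model order")
        try:
            inv.append(np.linalg.inv(W))
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(f"demixing matrix of run {i} is singular") from e
    out = np.empty(R)
    for i in range(R):
        vals = [isi(runs[j] @ inv[i]) for j in range(R) if j != i]
        out[i] = float(np.mean(vals))
    return out


@dataclass
class ConsistencyResult:
    """Cross-ISI distributions per candidate model order.

    ``table`` is tidy (order, run, cross_isi); ``shortlist`` flags orders with
    relatively small median and spread; ``best_run_index`` is the run with the
    smallest cross-ISI within ``best_order``.
    """

    orders: list[int]
    table: pd.DataFrame
    best_order: int
    best_run_index: int
    shortlist: list[int] = field(default_factory=list)
    n_runs: int = 0
    runs: dict[int, list] = field(default_factory=dict, repr=False)


def order_selection(data_builder, orders, runs_per_order: int,
                    table: EntropyBoundTable | None = None,
                    seed: int | None = None, max_iterations: int = 256,
                    tolerance: float = 1e-5) -> ConsistencyResult:
    """Cross-ISI model-order scan.

    For each candidate order the raw data (``data_builder`` may be the raw
    channels-by-samples matrix itself or a callable returning it) is whitened
    to that order and ICA-EBM is run ``runs_per_order`` times from seeded
    random initializations; the per-run cross-ISI distribution is tabulated.
    Orders exceeding the data rank are skipped with a warning.  The shortlist
    contains orders whose median cross-ISI is within 0.02 of the smallest and
    whose IQR is at most twice the smallest IQR among those; the final choice
    is left to the caller.
    """
    import warnings

    orders = list(orders)
    if not orders:
        raise ValueError("orders list is empty")
    if runs_per_order < 2:
        raise ValueError("runs_per_order must be >= 2")
    raw = data_builder() if callable(data_builder) else np.asarray(data_builder)
    if table is None:
        table = default_table()
    rng = np.random.default_rng(seed)
    records = []
    per_order_runs: dict[int, list] = {}
    kept_orders = []
    for order in orders:
        try:
            data = whiten(raw, order)
        except ValueError as e:
            warnings.warn(f"model order {order} skipped: {e}", RuntimeWarning)
            continue
        kept_orders.append(order)
        Ws = []
        for run in range(runs_per_order):
            run_seed = int(rng.integers(0, 2**31 - 1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                state = ica_ebm_fit(data, table, seed=run_seed,
                                    max_iterations=max_iterations,
                                    tolerance=tolerance)
            Ws.append(state.W)
        ci = cross_isi(Ws)
        per_order_runs[order] = Ws
        for run, v in enumerate(ci):
            records.append({"order": order, "run": run, "cross_isi": v})
    if not kept_orders:
        raise ValueError("no feasible model order")
    df = pd.DataFrame.from_records(records)
    med = df.groupby("order")["cross_isi"].median()
    iqr = df.groupby("order")["cross_isi"].quantile(0.75) \
        - df.groupby("order")["cross_isi"].quantile(0.25)
    near = med[med <= med.min() + 0.02].index
    shortlist = [int(o) for o in near
                 if iqr[o] <= 2.0 * max(iqr[near].min(), 1e-12)]
    best_order = int(med.idxmin())
    sub = df[df["order"] == best_order]
    best_run = int(sub.loc[sub["cross_isi"].idxmin(), "run"])
    return ConsistencyResult(orders=kept_orders, table=df,
                             best_order=best_order, best_run_index=best_run,
                             shortlist=shortlist, n_runs=runs_per_order,
                             runs=per_order_runs)
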