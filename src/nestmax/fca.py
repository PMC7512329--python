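"""Fitness-complexity ranking of bipartite networks.

The algorithm iterates, from the uniform initial condition F_i = Q_a = 1,

    F~_i(n) = sum_a B_ia Q_a(n-1)
    Q~_a(n) = 1 / sum_i (B_ia / F_i(n-1))

followed by normalization of both score vectors by their mean.  Row-node
scores (fitness) reward diversification: a row's score is the sum of its
partners' complexities.  Column-node scores (complexity) are harmonically
penalized by low-fitness partners, so a column served by any generalist ends
up with low complexity.  Sorting rows by decreasing fitness and columns by
increasing complexity packs the matrix into a triangular, nested shape.

The fixed point of the map can drive many scores to zero (slowly, and
dependent on matrix density and shape), so convergence is declared on the
*ranking*: stop at the smallest n* where the Spearman correlation between the
scores at n* and at n* + delta_n exceeds 1 - 1e-3 on both sides.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
import logging

import numpy as np
from scipy.stats import spearmanr

from .matrix import IncidenceMatrix, Ranking

__all__ = ["FCAState", "fca_step", "fca_converge", "fca_fixed", "fca_ranking", "spearman"]

logger = logging.getLogger(__name__)

#: scores are floored here before entering the reciprocal sum; the ranking
#: stop rule normally triggers long before any score decays this far
SCORE_FLOOR = 1e-280

RHO_THRESHOLD = 1.0 - 1e-3


@dataclass(frozen=True)
class FCAState:
    """Fitness/complexity score vectors plus iteration diagnostics."""

    F: np.ndarray  # N row-node fitness scores, mean 1
    Q: np.ndarray  # M column-node complexity scores, mean 1
    n: int  # iterations performed so far
    n_star: int | None = None  # stopping iteration (scores reported at n_star + delta_n)
    delta_n: int | None = None
    converged: bool = False
    rho_F: float | None = None
    rho_Q: float | None = None

    def __post_init__(self):
        for name in ("F", "Q"):
            v = np.asarray(getattr(self, name), dtype=float)
            v.setflags(write=False)
            object.__setattr__(self, name, v)

    @classmethod
    def initial(cls, m: IncidenceMatrix) -> "FCAState":
        return cls(F=np.ones(m.n_rows), Q=np.ones(m.n_cols), n=0)


def fca_step(m: IncidenceMatrix, state: FCAState) -> FCAState:
    """One update of the fitness-complexity map, reading the previous scores."""
    b = m.entries.astype(float)
    f_prev = np.maximum(state.F, SCORE_FLOOR)
    if (state.F < SCORE_FLOOR).any():
        logger.warning("fitness underflow floor hit at iteration %d", state.n)
    f_new = b @ state.Q
    q_new = 1.0 / (b.T @ (1.0 / f_prev))
    f_new = f_new / f_new.mean()
    q_new = q_new / q_new.mean()
    return FCAState(F=f_new, Q=q_new, n=state.n + 1, delta_n=state.delta_n)


def spearman(a, b) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns nan when either vector has zero variance (the coefficient is
    undefined there), which no valid rho in [-1, 1] can be confused with.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.shape[0] < 2:
        raise ValueError("spearman requires two equal-length vectors of length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(spearmanr(a, b).statistic)


def _ranking_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rho for convergence checks; two all-tied vectors agree trivially."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0
    rho = spearman(a, b)
    return -np.inf if np.isnan(rho) else rho


def fca_converge(
    m: IncidenceMatrix,
    delta_n: int = 10,
    max_iter: int = 5000,
) -> FCAState:
    """Iterate until the ranking stabilizes over a ``delta_n`` look-ahead window.

    Returns the state at ``n* + delta_n`` (the later, more converged end of
    the window), carrying ``n_star`` and the two Spearman coefficients.
    """
    if delta_n < 1:
        raise ValueError("delta_n must be >= 1")
    if (m.row_degrees == 0).any() or (m.col_degrees == 0).any():
        raise ValueError("matrix has empty rows or columns; clean it with drop_empty() first")
    state = FCAState.initial(m)
    # buffer of the last delta_n + 1 score pairs; candidate n* >= 1
    history: deque = deque(maxlen=delta_n + 1)
    rho_f = rho_q = -np.inf
    while state.n < max_iter:
        state = fca_step(m, state)
        history.append((state.F, state.Q))
        n_star = state.n - delta_n
        if n_star >= 1 and len(history) == delta_n + 1:
            f_old, q_old = history[0]
            rho_f = _ranking_agreement(f_old, state.F)
            rho_q = _ranking_agreement(q_old, state.Q)
            if rho_f > RHO_THRESHOLD and rho_q > RHO_THRESHOLD:
                return FCAState(
                    F=state.F, Q=state.Q, n=state.n, n_star=n_star, delta_n=delta_n,
                    converged=True, rho_F=float(rho_f), rho_Q=float(rho_q),
                )
    raise RuntimeError(
        f"fitness-complexity ranking did not stabilize within {max_iter} iterations "
        f"(last rho_F={rho_f:.6f}, rho_Q={rho_q:.6f})"
    )


def fca_fixed(m: IncidenceMatrix, n_iter: int = 100) -> FCAState:
    """Run a fixed number of iterations (no ranking-based stop rule)."""
    state = FCAState.initial(m)
    for _ in range(n_iter):
        state = fca_step(m, state)
    return FCAState(F=state.F, Q=state.Q, n=state.n, n_star=n_iter, converged=True)


def fca_ranking(state: FCAState, m: IncidenceMatrix) -> Ranking:
    """Ranking from converged scores.

    Rows by decreasing fitness (fittest = rank 1, top); columns by increasing
    complexity, so the least complex — most generalist — column sits left.
    Ties broken by decreasing degree, then input order.
    """
    n, mm = m.n_rows, m.n_cols
    idx = np.arange(n)
    # np.lexsort sorts by the last key first
    row_sorted = np.lexsort((idx, -m.row_degrees, -state.F))
    row_order = np.empty(n, dtype=np.int64)
    row_order[row_sorted] = np.arange(1, n + 1)
    idx = np.arange(mm)
    col_sorted = np.lexsort((idx, -m.col_degrees, state.Q))
    col_order = np.empty(mm, dtype=np.int64)
    col_order[col_sorted] = np.arange(1, mm + 1)
    return Ranking(row_order, col_order)
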