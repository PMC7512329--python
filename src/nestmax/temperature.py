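"""Nestedness temperature of a ranked matrix.

Given a ranked matrix, its *unexpected* elements are the empty cells in the
expected-filled region (on or above the line of perfect nestedness) and the
filled cells in the expected-empty region (below it).  Each unexpected cell
contributes the squared relative distance ``(d/D)^2`` of its center from the
line, measured along a probe line of slope -1; the total unexpectedness is

    U = (1 / (N M)) * sum over unexpected cells of (d / D)^2

and the temperature is ``T = 100 U / Umax`` with the conventional constant
``Umax = 0.04145``.  A perfectly nested matrix has T = 0; random, noisy
matrices have large T.  T is not clamped at 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isocline import Isocline, calibrated_isocline
from .matrix import IncidenceMatrix, Ranking, reorder

__all__ = ["UMAX", "UnexpectedCell", "TemperatureResult", "classify_cells", "temperature", "unexpectedness"]

#: normalization constant for the 0-100 temperature scale
UMAX = 0.04145


@dataclass(frozen=True)
class UnexpectedCell:
    row_rank: int
    col_rank: int
    kind: str  # "absence-in-filled-region" | "presence-in-empty-region"
    d: float
    D: float


@dataclass(frozen=True)
class TemperatureResult:
    """Unexpected-cell set with per-cell distances, unexpectedness U and temperature T."""

    unexpected_cells: tuple
    U: float
    T: float
    p: float
    n_rows: int
    n_cols: int

    @property
    def n_unexpected(self) -> int:
        return len(self.unexpected_cells)


def _check_no_empty_lines(m: IncidenceMatrix) -> None:
    if (m.row_degrees == 0).any() or (m.col_degrees == 0).any():
        raise ValueError(
            "matrix has empty rows or columns; clean it with drop_empty() first"
        )


def classify_cells(m: IncidenceMatrix, r: Ranking, iso: Isocline):
    """Unexpected cells of the reordered matrix, with their (d, D) distances.

    A cell is expected-filled iff its center lies on or above the isocline;
    centers exactly on the line count as expected-filled (their d = 0, so they
    contribute nothing either way).
    """
    if iso.n_rows != m.n_rows or iso.n_cols != m.n_cols:
        raise ValueError("isocline geometry does not match the matrix")
    if abs(iso.fill - m.fill) > 1e-12:
        raise ValueError(
            f"isocline calibrated for fill {iso.fill:.6f} but matrix fill is {m.fill:.6f}"
        )
    ranked = reorder(m, r)
    expected = iso.expected_mask
    filled = ranked.entries.astype(bool)
    d_grid, big_d_grid = iso.distance_grids
    cells = []
    for i, a in zip(*np.nonzero(expected != filled)):
        kind = "absence-in-filled-region" if expected[i, a] else "presence-in-empty-region"
        cells.append(
            UnexpectedCell(int(i) + 1, int(a) + 1, kind, float(d_grid[i, a]), float(big_d_grid[i, a]))
        )
    return tuple(cells)


def unexpectedness(entries: np.ndarray, iso: Isocline) -> float:
    """Fast U for already-reordered binary entries (vectorized hot path).

    Shares the per-geometry ``(d/D)^2`` grid, so evaluating many orderings of
    the same matrix costs one masked sum each.
    """
    mismatch = iso.expected_mask != entries.astype(bool)
    return float(iso.unexpectedness_grid[mismatch].sum()) / (iso.n_rows * iso.n_cols)


def temperature(m: IncidenceMatrix, r: Ranking | None = None) -> TemperatureResult:
    """Temperature T of matrix *m* under ranking *r* (identity by default).

    The isocline is calibrated at the matrix's own fill (memoized per
    (N, M, L); clamped at the bracket edge for fills no finite p attains).
    """
    _check_no_empty_lines(m)
    if r is None:
        r = Ranking.identity(m.n_rows, m.n_cols)
    iso = calibrated_isocline(m.n_rows, m.n_cols, m.n_links)
    cells = classify_cells(m, r, iso)
    nm = m.n_rows * m.n_cols
    u = sum((c.d / c.D) ** 2 for c in cells) / nm
    return TemperatureResult(
        unexpected_cells=cells,
        U=u,
        T=100.0 * u / UMAX,
        p=iso.p,
        n_rows=m.n_rows,
        n_cols=m.n_cols,
    )


def temperature_of_entries(entries: np.ndarray, iso: Isocline) -> float:
    """Temperature from already-reordered entries (hot path for optimizers)."""
    return 100.0 * unexpectedness(entries, iso) / UMAX
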