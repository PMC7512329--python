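"""The line of perfect nestedness (isocline) and its area calibration.

In the unit square, with the generalist column edge at ``x = 0`` and the
generalist row edge at ``y = 1``, the line of perfect nestedness for an
``N x M`` matrix of fill ``Phi`` is the shape function

    f(x; p) = 0.5/N + ((N-1)/N) * [1 - (1 - (M x - 0.5)/(M - 1))^p]^(1/p)

on the band ``x in [0.5/M, (M-0.5)/M]``, extended flat to the unit-square
edges.  The single shape parameter ``p > 0`` is calibrated so that the area
*above* the curve over (0, 1) equals the fill.  Cells whose centers lie above
(or on) the curve are expected to be filled in a perfectly nested matrix.

The area above the curve is strictly decreasing in ``p`` (``p -> 0`` flattens
the curve onto ``y = 0.5/N``; ``p -> inf`` pushes it up to ``y = (N-0.5)/N``),
so sparse matrices calibrate to large ``p`` and dense matrices to small ``p``.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "Isocline",
    "solve_isocline",
    "cell_coordinates",
    "cell_distances",
    "calibrated_isocline",
]

#: cells whose center is within this distance of the curve count as lying on it
TIE_TOL = 1e-9

_AREA_TOL = 1e-8
_BRACKET = (1e-4, 1e4)
_BRACKET_MAX = (1e-8, 1e8)


def _band_shape(u, p: float):
    """[1 - (1 - u)^p]^(1/p) on u in [0, 1]; monotone increasing, h(0)=0, h(1)=1."""
    u = np.clip(u, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        return (1.0 - (1.0 - u) ** p) ** (1.0 / p)


@dataclass(frozen=True)
class Isocline:
    """Calibrated line of perfect nestedness for a given (N, M, fill).

    ``clamped`` flags fills outside the area range attainable by any finite
    ``p`` (possible for very small or very dense matrices), in which case
    ``p`` sits at the bracket edge and ``area_residual`` records the gap.
    """

    p: float
    n_rows: int
    n_cols: int
    fill: float
    clamped: bool = False
    area_residual: float = 0.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.p <= 0:
            raise ValueError("shape parameter p must be positive")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("isocline requires N >= 2 and M >= 2")

    def value(self, x):
        """f(x; p) with flat extension outside the band of cell centers."""
        n, m = self.n_rows, self.n_cols
        u = (m * np.asarray(x, dtype=float) - 0.5) / (m - 1)
        return 0.5 / n + (n - 1) / n * _band_shape(u, self.p)

    def value_at_col(self, col_rank):
        """f at the center of column *col_rank* (exact at the band endpoints)."""
        n, m = self.n_rows, self.n_cols
        u = (np.asarray(col_rank) - 1) / (m - 1)
        return 0.5 / n + (n - 1) / n * _band_shape(u, self.p)

    @property
    def area_above(self) -> float:
        """Measure of the expected-filled region (area above the curve)."""
        return _area_above(self.p, self.n_rows, self.n_cols)

    # -- cached per-geometry grids (independent of any particular matrix) ----

    @property
    def col_values(self) -> np.ndarray:
        if "col_values" not in self._cache:
            vals = self.value_at_col(np.arange(1, self.n_cols + 1))
            vals.setflags(write=False)
            self._cache["col_values"] = vals
        return self._cache["col_values"]

    @property
    def row_heights(self) -> np.ndarray:
        if "row_heights" not in self._cache:
            n = self.n_rows
            y = (n - np.arange(1, n + 1) + 0.5) / n
            y.setflags(write=False)
            self._cache["row_heights"] = y
        return self._cache["row_heights"]

    @property
    def expected_mask(self) -> np.ndarray:
        """Boolean (N, M) grid: cell center on or above the curve."""
        if "expected_mask" not in self._cache:
            mask = self.row_heights[:, None] >= self.col_values[None, :] - TIE_TOL
            mask.setflags(write=False)
            self._cache["expected_mask"] = mask
        return self._cache["expected_mask"]

    @property
    def distance_grids(self):
        """Per-cell ``(d, D)`` grids of shape (N, M).

        ``d`` and ``D`` depend only on the cell position in the ranked matrix,
        never on the matrix content, so they are computed once per geometry.
        """
        if "distance_grids" not in self._cache:
            n, m = self.n_rows, self.n_cols
            d = np.empty((n, m))
            big_d = np.empty((n, m))
            for i in range(1, n + 1):
                for a in range(1, m + 1):
                    x, y = cell_coordinates(i, a, n, m)
                    d[i - 1, a - 1], big_d[i - 1, a - 1] = cell_distances(x, y, self)
            d.setflags(write=False)
            big_d.setflags(write=False)
            self._cache["distance_grids"] = (d, big_d)
        return self._cache["distance_grids"]

    @property
    def unexpectedness_grid(self) -> np.ndarray:
        """Per-cell contribution ``(d/D)^2`` to U, should the cell be unexpected."""
        if "unexpectedness_grid" not in self._cache:
            d, big_d = self.distance_grids
            grid = (d / big_d) ** 2
            grid.setflags(write=False)
            self._cache["unexpectedness_grid"] = grid
        return self._cache["unexpectedness_grid"]


def _area_above(p: float, n: int, m: int) -> float:
    """Area above the flat-extended curve over (0, 1), by adaptive quadrature."""
    band_integral, _ = quad(_band_shape, 0.0, 1.0, args=(p,), epsabs=1e-12, epsrel=1e-12, limit=200)
    integral_f = (
        (0.5 / m) * (0.5 / n)
        + ((m - 1) / m) * (0.5 / n + (n - 1) / n * band_integral)
        + (0.5 / m) * ((n - 0.5) / n)
    )
    return 1.0 - integral_f


def solve_isocline(
    n_rows: int,
    n_cols: int,
    fill: float,
    *,
    area_tol: float = _AREA_TOL,
    clamp: bool = False,
) -> Isocline:
    """Calibrate the shape parameter p so the area above the curve equals *fill*.

    Root-finding over ``p in [1e-4, 1e4]`` (expanded geometrically to
    ``[1e-8, 1e8]`` when needed).  Fills outside the attainable area range
    raise an error reporting that range, unless ``clamp=True``, in which case
    the bracket-edge isocline is returned with ``clamped=True`` and the area
    residual recorded; this is the policy used when evaluating the temperature
    of matrices whose fill no finite p can match.
    """
    n, m = int(n_rows), int(n_cols)
    if n < 2 or m < 2:
        raise ValueError("shape function undefined for N < 2 or M < 2 (M - 1 in denominator)")
    if not 0.0 < fill < 1.0:
        raise ValueError(f"fill must lie strictly between 0 and 1, got {fill}")

    lo, hi = _BRACKET
    # area is decreasing in p: g(lo) is the maximum attainable, g(hi) the minimum
    g = lambda p: _area_above(p, n, m) - fill
    g_lo, g_hi = g(lo), g(hi)
    while g_lo < 0 and lo > _BRACKET_MAX[0]:
        lo = max(lo * 1e-2, _BRACKET_MAX[0])
        g_lo = g(lo)
    while g_hi > 0 and hi < _BRACKET_MAX[1]:
        hi = min(hi * 1e2, _BRACKET_MAX[1])
        g_hi = g(hi)

    if g_lo < 0 or g_hi > 0:  # fill outside attainable range
        edge, resid = (lo, g_lo) if g_lo < 0 else (hi, g_hi)
        if abs(resid) <= area_tol:
            return Isocline(edge, n, m, fill, clamped=False, area_residual=resid)
        if clamp:
            return Isocline(edge, n, m, fill, clamped=True, area_residual=resid)
        raise ValueError(
            f"fill {fill:.6f} outside the attainable area range "
            f"[{_area_above(hi, n, m):.6f}, {_area_above(lo, n, m):.6f}] for {n}x{m}"
        )

    p = brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16)
    resid = g(p)
    if abs(resid) > area_tol:  # pragma: no cover - defensive
        raise RuntimeError(f"calibration failed: |area - fill| = {abs(resid):.3e}")
    return Isocline(p, n, m, fill, area_residual=resid)


@functools.lru_cache(maxsize=4096)
def calibrated_isocline(n_rows: int, n_cols: int, n_links: int) -> Isocline:
    """Memoized clamped calibration at fill ``L / (N M)``.

    Reordering never changes (N, M, L), so rankers evaluating many orderings
    of one matrix share a single calibrated geometry (and its cached grids).
    """
    return solve_isocline(n_rows, n_cols, n_links / (n_rows * n_cols), clamp=True)


def cell_coordinates(row_rank: int, col_rank: int, n_rows: int, n_cols: int):
    """Unit-square center of the cell at (row rank, col rank).

    ``x = (col_rank - 0.5)/M`` from the generalist (left) edge and
    ``y = (N - row_rank + 0.5)/N`` in Cartesian orientation, so the most
    generalist row (rank 1) has the largest y.
    """
    if not 1 <= row_rank <= n_rows:
        raise ValueError(f"row rank {row_rank} out of range 1..{n_rows}")
    if not 1 <= col_rank <= n_cols:
        raise ValueError(f"col rank {col_rank} out of range 1..{n_cols}")
    return (col_rank - 0.5) / n_cols, (n_rows - row_rank + 0.5) / n_rows


def cell_distances(x: float, y: float, iso: Isocline):
    """Distances (d, D) for the probe line of slope -1 through cell center (x, y).

    ``D = sqrt(2) (x + y)`` is the length between the probe line's axis
    intercepts ``(x+y, 0)`` and ``(0, x+y)``, taken literally even when the
    intercepts fall outside the unit square.  ``d`` is the distance from the
    center to the intersection of the probe line with the flat-extended
    isocline; the gap ``(x + y - t) - f(t)`` is strictly decreasing along the
    line, so the intersection is unique.
    """
    s = x + y
    big_d = math.sqrt(2.0) * s
    gap = lambda t: (s - t) - float(iso.value(t))
    g0 = gap(0.0)
    if abs(g0) < 1e-14:
        t_star = 0.0
    elif g0 < 0:  # pragma: no cover - impossible for in-square cell centers
        raise RuntimeError(
            "probe line does not intersect the extended isocline; calibration bug"
        )
    else:
        t_star = brentq(gap, 0.0, s, xtol=1e-12, rtol=8.9e-16)
    d = math.sqrt(2.0) * abs(t_star - x)
    if d < 1e-10:
        d = 0.0  # center numerically on the curve
    return d, big_d
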