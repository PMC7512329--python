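"""Synthetic fixture generators with known ground truth.

These emulate the inputs every other module consumes: perfectly nested
matrices consistent with the isocline, noise-corrupted nested matrices at
controlled fill, uniform random matrices, and weighted trade tables with a
nested capability structure.  All generators take explicit seeds and never
touch global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import functools

from .isocline import solve_isocline
from .matrix import IncidenceMatrix
from .rca import WeightedTradeMatrix

__all__ = [
    "NestedSpec",
    "perfect_nested",
    "noisy_nested",
    "random_matrix",
    "nested_trade_table",
]


@dataclass(frozen=True)
class NestedSpec:
    """Parameters of a (noisy-)nested synthetic matrix."""

    n_rows: int
    n_cols: int
    fill: float  # target fill; the realized fill of the nested mask may drift above it
    noise: float = 0.0  # fraction of links moved by fill-conserving swaps
    seed: int | None = None

    def __post_init__(self):
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("need at least a 2x2 matrix")
        if not 0.0 < self.fill < 1.0:
            raise ValueError("target fill must lie strictly between 0 and 1")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise fraction must lie in [0, 1)")


def _mask_at_fill(n: int, m: int, fill: float) -> np.ndarray:
    iso = solve_isocline(n, m, fill, clamp=True)
    return np.asarray(iso.expected_mask)


def perfect_nested(spec: NestedSpec) -> IncidenceMatrix:
    """Perfectly nested matrix whose filled set is exactly the expected-filled
    region of the isocline calibrated at its *own* fill.

    Construction: fill the cells above the curve calibrated at the target
    fill, recalibrate at the realized fill, and iterate to a mask-level fixed
    point (the cell-counted fill systematically exceeds the continuous
    calibration area, so the realized fill settles above the target; it is
    available as ``.fill`` on the result).  By construction the degree-ordered
    matrix has zero temperature and every row's partner set is nested inside
    that of any higher-degree row.
    """
    mask = _perfect_mask(spec.n_rows, spec.n_cols, spec.fill)
    return IncidenceMatrix.from_array(np.asarray(mask, dtype=np.uint8))


@functools.lru_cache(maxsize=256)
def _perfect_mask(n: int, m: int, fill: float) -> np.ndarray:
    nm = n * m

    def count_above(k: int) -> int:
        """Cells above the curve calibrated at fill k/(N M); nondecreasing in k."""
        return int(_mask_at_fill(n, m, k / nm).sum())

    # direct iteration converges in a handful of steps for small matrices
    mask = _mask_at_fill(n, m, fill)
    seen = set()
    for _ in range(60):
        key = mask.tobytes()
        nxt = _mask_at_fill(n, m, mask.sum() / nm)
        if (nxt == mask).all():
            mask.setflags(write=False)
            return mask
        if key in seen:
            break
        seen.add(key)
        mask = nxt

    # slow upward drift or a cycle: bisect for the crossing of count_above(k) - k,
    # then scan its neighborhood for an exactly self-consistent link count
    lo, hi = int(mask.sum()), nm - 1
    if count_above(lo) >= lo:
        while lo < hi:
            mid = (lo + hi) // 2
            if count_above(mid) > mid:
                lo = mid + 1
            else:
                hi = mid
    for k in range(max(1, lo - 4 * m), min(nm - 1, lo + 4 * m) + 1):
        if count_above(k) == k:
            cand = _mask_at_fill(n, m, k / nm)
            cand.setflags(write=False)
            return cand
    raise RuntimeError(
        f"no isocline-consistent nested mask found near fill {fill} for {n}x{m}"
    )


def noisy_nested(spec: NestedSpec) -> IncidenceMatrix:
    """Perfectly nested matrix corrupted by ``ceil(noise * L)`` fill-swaps.

    Each swap moves one randomly chosen link to a randomly chosen empty cell,
    so L (and hence the isocline) is held fixed across noise levels; only the
    ordering difficulty changes.  Swaps may empty a row or column; clean with
    ``drop_empty`` before ranking.
    """
    base = perfect_nested(spec)
    entries = np.array(base.entries)
    n_swaps = int(np.ceil(spec.noise * base.n_links))
    if n_swaps == 0:
        return base
    rng = np.random.default_rng(spec.seed)
    for _ in range(n_swaps):
        ones = np.flatnonzero(entries)
        zeros = np.flatnonzero(entries == 0)
        if zeros.size == 0:
            raise ValueError("no empty cells available for a swap")
        src = ones[rng.integers(ones.size)]
        dst = zeros[rng.integers(zeros.size)]
        entries.flat[src] = 0
        entries.flat[dst] = 1
    return IncidenceMatrix(entries, base.row_labels, base.col_labels)


def random_matrix(
    n_rows: int,
    n_cols: int,
    fill: float,
    seed: int | None = None,
    max_retries: int = 1000,
) -> IncidenceMatrix:
    """Uniform random matrix with exactly ``round(fill * N * M)`` links.

    Draws are redrawn (up to *max_retries*) until no row or column is empty.
    """
    if not 0.0 < fill <= 1.0:
        raise ValueError("fill must lie in (0, 1]")
    nm = n_rows * n_cols
    n_links = int(round(fill * nm))
    if n_links < max(n_rows, n_cols):
        raise ValueError(
            f"{n_links} links cannot cover {n_rows} rows and {n_cols} columns"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        flat = rng.choice(nm, size=n_links, replace=False)
        entries = np.zeros(nm, dtype=np.uint8)
        entries[flat] = 1
        entries = entries.reshape(n_rows, n_cols)
        if entries.sum(axis=1).min() > 0 and entries.sum(axis=0).min() > 0:
            return IncidenceMatrix.from_array(entries)
    raise RuntimeError(
        f"could not draw a {n_rows}x{n_cols} matrix with {n_links} links and "
        f"no empty lines in {max_retries} attempts"
    )


def nested_trade_table(
    n_rows: int,
    n_cols: int,
    fill: float,
    dispersion: float = 0.5,
    seed: int | None = None,
) -> WeightedTradeMatrix:
    """Weighted trade table whose capability structure is a nested mask.

    Volumes are ``w_ia = c_i * p_a * exp(eps)`` on the cells of a perfectly
    nested capability mask and exactly zero elsewhere, with heavy-tailed
    (log-normal) country sizes ``c_i`` and product sizes ``p_a`` and
    log-normal noise ``eps`` of standard deviation *dispersion*.  Off-mask
    cells can never gain a link under RCA binarization (their volume is 0);
    on-mask cells recover the mask up to RCA threshold effects at the
    generalist corner.
    """
    rng = np.random.default_rng(seed)
    # the capability mask only needs to be perfectly nested, not an exact
    # isocline fixed point; for large tables the one-shot mask is used since
    # the fixed-point search cost scales poorly and RCA thresholding breaks
    # exact isocline compatibility anyway
    if n_rows * n_cols <= 5000:
        mask = perfect_nested(NestedSpec(n_rows, n_cols, fill)).entries.astype(float)
    else:
        mask = _mask_at_fill(n_rows, n_cols, fill).astype(float)
    c = rng.lognormal(mean=0.0, sigma=1.0, size=n_rows)
    p = rng.lognormal(mean=0.0, sigma=1.0, size=n_cols)
    eps = rng.normal(0.0, dispersion, size=(n_rows, n_cols))
    weights = np.outer(c, p) * np.exp(eps) * mask
    return WeightedTradeMatrix(
        weights,
        tuple(f"country_{i + 1}" for i in range(n_rows)),
        tuple(f"product_{a + 1}" for a in range(n_cols)),
    )
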