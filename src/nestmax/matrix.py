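"""Binary bipartite incidence matrices: data model, I/O and elementary operations.

An :class:`IncidenceMatrix` holds the N x M binary matrix ``B`` of a bipartite
network (``B[i, a] = 1`` iff row-node *i* interacts with column-node *a*)
together with its row and column labels.  A :class:`Ranking` is a pair of
permutations assigning rank positions to rows and columns; rank 1 is the most
generalist node and is placed top/left when the matrix is reordered.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceMatrix",
    "Ranking",
    "read_incidence",
    "write_incidence",
    "density",
    "drop_empty",
    "reorder",
    "degree_ranking",
]


def _check_unique(labels, side: str) -> None:
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if list(labels).count(x) > 1})
        raise ValueError(f"duplicate {side} labels: {dupes}")


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary N x M incidence matrix with row/column labels.

    Parameters
    ----------
    entries
        Array of shape (N, M) with entries in {0, 1}.
    row_labels, col_labels
        Unique string identifiers, one per row / column.
    """

    entries: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self):
        entries = np.asarray(self.entries)
        if entries.ndim != 2:
            raise ValueError("entries must be a 2-d array")
        if entries.shape[0] < 1 or entries.shape[1] < 1:
            raise ValueError("matrix must have at least one row and one column")
        if not np.isin(entries, (0, 1)).all():
            raise ValueError("entries must be exactly 0 or 1")
        entries = entries.astype(np.uint8)
        entries.setflags(write=False)
        object.__setattr__(self, "entries", entries)
        row_labels = tuple(str(x) for x in self.row_labels)
        col_labels = tuple(str(x) for x in self.col_labels)
        if len(row_labels) != entries.shape[0]:
            raise ValueError("row_labels length does not match entries")
        if len(col_labels) != entries.shape[1]:
            raise ValueError("col_labels length does not match entries")
        _check_unique(row_labels, "row")
        _check_unique(col_labels, "column")
        object.__setattr__(self, "row_labels", row_labels)
        object.__setattr__(self, "col_labels", col_labels)

    @classmethod
    def from_array(cls, entries, row_labels=None, col_labels=None) -> "IncidenceMatrix":
        """Build from an array, auto-generating ``R1.. / C1..`` labels."""
        entries = np.asarray(entries)
        n, m = entries.shape
        if row_labels is None:
            row_labels = [f"R{i + 1}" for i in range(n)]
        if col_labels is None:
            col_labels = [f"C{a + 1}" for a in range(m)]
        return cls(entries, tuple(row_labels), tuple(col_labels))

    @property
    def n_rows(self) -> int:
        return self.entries.shape[0]

    @property
    def n_cols(self) -> int:
        return self.entries.shape[1]

    @property
    def n_links(self) -> int:
        """Number of links L (count of 1-entries)."""
        return int(self.entries.sum())

    @property
    def fill(self) -> float:
        """Density Phi = L / (M N)."""
        return self.n_links / (self.n_rows * self.n_cols)

    @property
    def row_degrees(self) -> np.ndarray:
        return self.entries.sum(axis=1)

    @property
    def col_degrees(self) -> np.ndarray:
        return self.entries.sum(axis=0)

    def transpose(self) -> "IncidenceMatrix":
        return IncidenceMatrix(self.entries.T, self.col_labels, self.row_labels)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"IncidenceMatrix(N={self.n_rows}, M={self.n_cols}, "
            f"L={self.n_links}, fill={self.fill:.4f})"
        )


@dataclass(frozen=True)
class Ranking:
    """A pair of rank permutations for rows and columns.

    ``row_order[i]`` is the 1-based rank position of input row *i*; rank 1 is
    the most generalist node (placed top/left).  Both vectors are bijections
    onto {1..N} and {1..M}.
    """

    row_order: np.ndarray
    col_order: np.ndarray

    def __post_init__(self):
        for name in ("row_order", "col_order"):
            vec = np.asarray(getattr(self, name), dtype=np.int64)
            n = vec.shape[0]
            if vec.ndim != 1 or n < 1:
                raise ValueError(f"{name} must be a non-empty 1-d vector")
            if sorted(vec.tolist()) != list(range(1, n + 1)):
                raise ValueError(f"{name} is not a permutation of 1..{n}")
            vec.setflags(write=False)
            object.__setattr__(self, name, vec)

    @classmethod
    def identity(cls, n_rows: int, n_cols: int) -> "Ranking":
        return cls(np.arange(1, n_rows + 1), np.arange(1, n_cols + 1))

    @property
    def row_permutation(self) -> np.ndarray:
        """Input row indices listed in rank order (rank 1 first)."""
        return np.argsort(self.row_order, kind="stable")

    @property
    def col_permutation(self) -> np.ndarray:
        return np.argsort(self.col_order, kind="stable")


def density(m: IncidenceMatrix) -> float:
    """Density Phi = L / (M N) of the network."""
    return m.fill


def reorder(m: IncidenceMatrix, r: Ranking) -> IncidenceMatrix:
    """Permute rows and columns of *m* so that rank 1 sits top/left."""
    if r.row_order.shape[0] != m.n_rows or r.col_order.shape[0] != m.n_cols:
        raise ValueError(
            f"ranking dimensions ({r.row_order.shape[0]}x{r.col_order.shape[0]}) "
            f"do not match matrix ({m.n_rows}x{m.n_cols})"
        )
    rp, cp = r.row_permutation, r.col_permutation
    return IncidenceMatrix(
        m.entries[np.ix_(rp, cp)],
        tuple(m.row_labels[i] for i in rp),
        tuple(m.col_labels[a] for a in cp),
    )


def drop_empty(m: IncidenceMatrix):
    """Strip all-zero rows and columns.

    Returns ``(matrix, dropped_row_labels, dropped_col_labels)``.  Zero-degree
    nodes collapse the fitness-complexity scores and violate the isocline
    construction's assumption that every line carries at least one link, so
    they are removed up front and re-appended at the worst ranks by callers
    that need a full ranking.
    """
    if m.n_links == 0:
        raise ValueError("empty network: matrix has no links")
    keep_r = m.row_degrees > 0
    keep_c = m.col_degrees > 0
    dropped_rows = tuple(l for l, k in zip(m.row_labels, keep_r) if not k)
    dropped_cols = tuple(l for l, k in zip(m.col_labels, keep_c) if not k)
    if not dropped_rows and not dropped_cols:
        return m, (), ()
    out = IncidenceMatrix(
        m.entries[np.ix_(np.flatnonzero(keep_r), np.flatnonzero(keep_c))],
        tuple(l for l, k in zip(m.row_labels, keep_r) if k),
        tuple(l for l, k in zip(m.col_labels, keep_c) if k),
    )
    return out, dropped_rows, dropped_cols


def _rank_by_decreasing(values: np.ndarray) -> np.ndarray:
    """1-based ranks by decreasing value; ties broken by input index (stable)."""
    order = np.argsort(-np.asarray(values), kind="stable")
    ranks = np.empty(len(order), dtype=np.int64)
    ranks[order] = np.arange(1, len(order) + 1)
    return ranks


def degree_ranking(m: IncidenceMatrix) -> Ranking:
    """Rank rows and columns by decreasing degree (stable ties)."""
    return Ranking(_rank_by_decreasing(m.row_degrees), _rank_by_decreasing(m.col_degrees))


# ---------------------------------------------------------------------------
# I/O
#
# matrix-csv: first row = column labels, first column = row labels, numeric
# cells (the web-of-life.es export dialect, which may carry interaction
# counts).  edge-list: TSV with columns row_label, col_label[, weight].
# ---------------------------------------------------------------------------


def read_incidence(
    path,
    dialect: str = "matrix-csv",
    binarize_threshold: float = 0.0,
    transpose: bool = False,
) -> IncidenceMatrix:
    """Read an incidence matrix from ``matrix-csv`` or ``edge-list`` format.

    Raw values strictly greater than *binarize_threshold* become links.  Some
    web-of-life datasets store plants as rows and others as columns; pass
    ``transpose=True`` to flip the orientation rather than guessing.
    """
    if dialect == "matrix-csv":
        m = _read_matrix_csv(path, binarize_threshold)
    elif dialect == "edge-list":
        m = _read_edge_list(path, binarize_threshold)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return m.transpose() if transpose else m


def _read_matrix_csv(path, threshold: float) -> IncidenceMatrix:
    try:
        df = pd.read_csv(path, index_col=0, header=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"cannot parse {path}: empty file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"cannot parse {path}: no data cells")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        raise ValueError(f"missing or ragged cells in {path}")
    return IncidenceMatrix(
        (values > threshold).astype(np.uint8),
        tuple(str(x) for x in df.index),
        tuple(str(x) for x in df.columns),
    )


def _read_edge_list(path, threshold: float) -> IncidenceMatrix:
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"cannot parse {path}: empty file") from exc
    if df.shape[1] not in (2, 3):
        raise ValueError(
            f"edge list {path} must have 2 or 3 tab-separated columns, got {df.shape[1]}"
        )
    if df.isna().any().any():
        raise ValueError(f"missing fields in edge list {path}")
    rows = list(dict.fromkeys(df[0]))  # first-appearance order
    cols = list(dict.fromkeys(df[1]))
    if df.shape[1] == 3:
        try:
            weights = df[2].astype(float).to_numpy()
        except ValueError as exc:
            raise ValueError(f"non-numeric weight in {path}: {exc}") from exc
    else:
        weights = np.ones(len(df))
    entries = np.zeros((len(rows), len(cols)), dtype=np.uint8)
    ri = {l: i for i, l in enumerate(rows)}
    ci = {l: a for a, l in enumerate(cols)}
    for (rl, cl), w in zip(zip(df[0], df[1]), weights):
        if w > threshold:
            entries[ri[rl], ci[cl]] = 1
    return IncidenceMatrix(entries, tuple(rows), tuple(cols))


def write_incidence(m: IncidenceMatrix, path) -> None:
    """Write *m* in matrix-csv format (round-trips with :func:`read_incidence`)."""
    df = pd.DataFrame(m.entries, index=list(m.row_labels), columns=list(m.col_labels))
    if isinstance(path, io.IOBase):
        df.to_csv(path)
    else:
        df.to_csv(path)
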