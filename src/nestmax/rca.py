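"""Revealed comparative advantage (RCA) binarization of weighted trade tables.

For export volumes ``w_ia`` (country i, product a, in US dollars), the RCA is

    R_ia = w_ia / <w_ia>,    <w_ia> = w_i * w_a / W,

where ``w_i`` and ``w_a`` are the country and product totals and ``W`` the
grand total.  A country is linked to a product in the binary country-product
network iff ``R_ia >= 1``: it exports the product more than expected from the
margins alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import IncidenceMatrix, drop_empty

__all__ = ["WeightedTradeMatrix", "rca", "rca_binarize", "read_trade_table"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightedTradeMatrix:
    """Non-negative N x M export-volume matrix with country/product labels."""

    weights: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ValueError("weights must be a 2-d array")
        if (w < 0).any():
            raise ValueError("export volumes must be non-negative")
        if w.sum() <= 0:
            raise ValueError("total export volume must be positive")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "row_labels", tuple(str(x) for x in self.row_labels))
        object.__setattr__(self, "col_labels", tuple(str(x) for x in self.col_labels))
        if len(self.row_labels) != w.shape[0] or len(self.col_labels) != w.shape[1]:
            raise ValueError("label lengths do not match weights")


def _drop_zero_margins(t: WeightedTradeMatrix) -> WeightedTradeMatrix:
    keep_r = t.weights.sum(axis=1) > 0
    keep_c = t.weights.sum(axis=0) > 0
    if keep_r.all() and keep_c.all():
        return t
    dropped = [l for l, k in zip(t.row_labels, keep_r) if not k] + [
        l for l, k in zip(t.col_labels, keep_c) if not k
    ]
    logger.info("dropping %d zero-volume rows/columns: %s", len(dropped), dropped)
    return WeightedTradeMatrix(
        t.weights[np.ix_(np.flatnonzero(keep_r), np.flatnonzero(keep_c))],
        tuple(l for l, k in zip(t.row_labels, keep_r) if k),
        tuple(l for l, k in zip(t.col_labels, keep_c) if k),
    )


def rca(t: WeightedTradeMatrix) -> np.ndarray:
    """RCA grid ``R_ia = w_ia * W / (w_i * w_a)``.

    Zero-margin rows/columns are dropped (and logged) before the division, so
    the returned grid matches the cleaned table's shape.
    """
    t = _drop_zero_margins(t)
    w = t.weights
    total = w.sum()
    return w * total / np.outer(w.sum(axis=1), w.sum(axis=0))


def rca_binarize(t: WeightedTradeMatrix, threshold: float = 1.0) -> IncidenceMatrix:
    """Binary incidence matrix of pairs with ``R_ia >= threshold``.

    The comparison is inclusive, and rows/columns left without links are
    stripped afterwards.
    """
    t = _drop_zero_margins(t)
    links = (rca(t) >= threshold).astype(np.uint8)
    m = IncidenceMatrix(links, t.row_labels, t.col_labels)
    cleaned, dropped_rows, dropped_cols = drop_empty(m)
    if dropped_rows or dropped_cols:
        logger.info(
            "RCA binarization left %d rows / %d cols without links; stripped",
            len(dropped_rows), len(dropped_cols),
        )
    return cleaned


def read_trade_table(path, year: int | None = None) -> WeightedTradeMatrix:
    """Read a TSV of (country, product, value) or (year, country, product, value).

    Values are export volumes; multiple records for one country-product pair
    (e.g. per-importer flows) are summed.  With a 4-column file, *year*
    selects the slice to keep.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] == 4:
        df.columns = ["year", "country", "product", "value"]
        if year is not None:
            df = df[df["year"].astype(int) == int(year)]
            if df.empty:
                raise ValueError(f"no records for year {year} in {path}")
    elif df.shape[1] == 3:
        df.columns = ["country", "product", "value"]
    else:
        raise ValueError(f"trade table {path} must have 3 or 4 tab-separated columns")
    df["value"] = df["value"].astype(float)
    pivot = df.pivot_table(index="country", columns="product", values="value",
                           aggfunc="sum", fill_value=0.0)
    return WeightedTradeMatrix(
        pivot.to_numpy(), tuple(pivot.index), tuple(pivot.columns)
    )
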