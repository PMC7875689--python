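"""Contingency tables, Pearson chi-square tests, and conditional percentages.

These are the descriptive building blocks for encouragement-by-outcome and
encouragement-by-usage summaries of an encouragement-design survey: observed
counts of one categorical variable against another, column (or row)
percentages, and the unweighted Pearson chi-square test of independence.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "chi_square_independence",
    "conditional_percentages",
    "format_p",
]


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c grid of observed counts with ordered level labels."""

    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-d grid")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)
        r, c = counts.shape
        object.__setattr__(
            self, "row_labels", tuple(self.row_labels) or tuple(range(r))
        )
        object.__setattr__(
            self, "col_labels", tuple(self.col_labels) or tuple(range(c))
        )
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValueError("label lengths must match the count grid shape")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def drop_empty_margins(self) -> "ContingencyTable":
        """Remove all-zero rows and columns (structurally absent levels)."""
        rk = self.row_totals > 0
        ck = self.col_totals > 0
        return ContingencyTable(
            self.counts[np.ix_(rk, ck)],
            tuple(l for l, k in zip(self.row_labels, rk) if k),
            tuple(l for l, k in zip(self.col_labels, ck) if k),
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    n: int
    expected: np.ndarray = field(repr=False)


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected cell counts under independence, from the observed margins."""
    n = table.total
    if n == 0:
        raise ValueError("contingency table is empty")
    return np.outer(table.row_totals, table.col_totals) / n


def chi_square_independence(table: ContingencyTable) -> ChiSquareResult:
    """Unweighted Pearson chi-square test of independence.

    statistic = sum (O - E)^2 / E with E from the observed margins, no
    continuity correction, df = (r-1)(c-1). An expected count of exactly zero
    (an empty margin) is a hard error; pool or drop that level first
    (``ContingencyTable.drop_empty_margins``). Expected counts below 5 only
    log a warning.
    """
    r, c = table.counts.shape
    if r < 2 or c < 2:
        raise ValueError("need at least a 2x2 table for the chi-square test")
    expected = expected_counts(table)
    if (expected == 0).any():
        raise ValueError(
            "expected count of zero (empty row or column margin); pool levels "
            "or call drop_empty_margins() before testing"
        )
    n_small = int((expected < 5).sum())
    if n_small:
        logger.warning("%d expected cell(s) below 5; chi-square may be inexact", n_small)
    statistic = float(((table.counts - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    p_value = float(stats.chi2.sf(statistic, df))
    return ChiSquareResult(statistic, df, p_value, table.total, expected)


def conditional_percentages(table: ContingencyTable, axis: str = "columns") -> np.ndarray:
    """Percentages conditional on a margin.

    ``axis="columns"`` divides each cell by its column total (each column sums
    to 100); ``axis="rows"`` divides by row totals. A zero margin yields NaN
    entries (flagged, never silently zero).
    """
    counts = table.counts.astype(float)
    if axis == "columns":
        tot = table.col_totals.astype(float)[np.newaxis, :]
    elif axis == "rows":
        tot = table.row_totals.astype(float)[:, np.newaxis]
    else:
        raise ValueError("axis must be 'rows' or 'columns'")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * counts / tot
    if np.isnan(pct).any():
        logger.warning("zero margin produced undefined percentage entries (NaN)")
    return pct


def format_p(p: float, decimals: int = 3) -> str:
    """Journal-style p-value formatting: ``.001``-style, ``<.001`` below 5e-4."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.0005:
        return "<.001"
    s = f"{p:.{decimals}f}"
    return s[1:] if s.startswith("0") else s
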