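"""Group-comparison statistics: chi-square on binned distributions,
pooled-variance two-sample t, and Pearson correlation.

The test statistics are computed from their defining formulas (the chi-square
pooling of sparse bins is specific to this pipeline); tail probabilities come
from the scipy.stats reference distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: reporting tiers used when annotating tables
SIGNIFICANCE_TIERS = (0.05, 0.01, 0.001)

EXPECTED_MIN = 5.0  # Cochran guidance: pool bins with expected count below this


@dataclass(frozen=True)
class StatResult:
    statistic_name: str  # chi_square | t | r
    value: float
    df: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def stars(self) -> str:
        for i, tier in enumerate(reversed(SIGNIFICANCE_TIERS)):
            if self.p_value < tier:
                return "*" * (len(SIGNIFICANCE_TIERS) - i)
        return ""


def pool_sparse_columns(table: np.ndarray, expected_min: float = EXPECTED_MIN) -> np.ndarray:
    """Merge columns whose expected count falls below ``expected_min`` in
    either row into the nearest lower-index column (column 0 merges upward).

    Repeats until every expected count clears the threshold or only one
    column remains.
    """
    table = np.asarray(table, dtype=float).copy()
    while table.shape[1] > 1:
        row_sums = table.sum(axis=1, keepdims=True)
        col_sums = table.sum(axis=0, keepdims=True)
        expected = row_sums * col_sums / table.sum()
        sparse = np.where((expected < expected_min).any(axis=0))[0]
        if sparse.size == 0:
            break
        j = int(sparse[0])
        target = j - 1 if j > 0 else 1
        table[:, target] += table[:, j]
        table = np.delete(table, j, axis=1)
    return table


def chi_square_independence(table, pool: bool = True) -> StatResult:
    """Pearson chi-square of independence on a 2 x K count table.

    Sparse columns are pooled first (see :func:`pool_sparse_columns`); no
    continuity correction is applied.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x K table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=1) <= 0).any():
        raise ValueError("both groups need at least one observation")
    if pool:
        table = pool_sparse_columns(table)
    table = table[:, table.sum(axis=0) > 0]
    k = table.shape[1]
    if k < 2:
        raise ValueError("fewer than 2 usable columns after pooling")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = k - 1
    return StatResult("chi_square", chi2, df, float(sps.chi2.sf(chi2, df)))


def two_sample_t(x, y) -> StatResult:
    """Pooled-variance (Student) two-sample t test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 values")
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return StatResult("t", 0.0, df, 1.0)
        raise ValueError("zero pooled variance with unequal means")
    t = diff / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    return StatResult("t", float(t), df, float(2.0 * sps.t.sf(abs(t), df)))


def pearson_correlation(x, y) -> StatResult:
    """Pearson r with the usual t-based two-sided significance test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.cov(x, y, ddof=1)[0, 1] / (sx * sy))
    r = max(-1.0, min(1.0, r))
    n = len(x)
    df = n - 2
    if abs(r) == 1.0:
        return StatResult("r", r, df, 0.0)
    t = r * math.sqrt(df / (1.0 - r * r))
    return StatResult("r", r, df, float(2.0 * sps.t.sf(abs(t), df)))


def mean_se(values) -> tuple[float, float]:
    """Arithmetic mean and standard error (sample sd / sqrt(n))."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values for a mean +- SE")
    return float(values.mean()), float(values.std(ddof=1) / math.sqrt(len(values)))
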