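"""Exact contingency-table tests and classical group comparisons.

The exact tests are implemented from first principles.  The two-sided
convention is the point-probability ("Fisher–Irwin") rule: the p-value is the
sum of the probabilities, under the (multivariate) hypergeometric null with
all margins fixed, of every table whose point probability does not exceed the
observed table's point probability (relative tie tolerance 1e-7).  The
Freeman–Halton test generalises this to r x c tables by exhaustive
enumeration of all tables with the observed margins, with probabilities
accumulated in log space; on a 2 x 2 input it reduces exactly to the Fisher
test.

Classical continuous-variable comparisons (t, Mann–Whitney, Kruskal–Wallis
with Bonferroni-corrected pairwise follow-ups, Spearman) are delegated to
scipy.stats behind a single dispatch function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import (
    DegenerateTableError,
    DomainError,
    EnumerationLimitError,
    UndefinedStatisticError,
)

#: relative tolerance for point-probability ties in the two-sided rule
TIE_RTOL = 1e-7
#: guard on the number of tables enumerated by the Freeman–Halton test
DEFAULT_MAX_TABLES = 10_000_000


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of non-negative integer counts with optional axis labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise DomainError(f"table must be at least 2x2, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise DomainError("counts must be integers")
            arr = np.round(arr).astype(np.int64)
        if (arr < 0).any():
            raise DomainError("counts must be non-negative")
        if arr.sum() == 0:
            raise DomainError("grand total must be positive")
        object.__setattr__(self, "counts", arr.astype(np.int64))
        if self.row_labels and len(self.row_labels) != arr.shape[0]:
            raise DomainError("row_labels length mismatch")
        if self.col_labels and len(self.col_labels) != arr.shape[1]:
            raise DomainError("col_labels length mismatch")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def require_positive_margins(self) -> None:
        if (self.row_margins == 0).any() or (self.col_margins == 0).any():
            raise DegenerateTableError(
                f"exact test undefined for zero margins (rows {self.row_margins.tolist()}, "
                f"cols {self.col_margins.tolist()})"
            )


def _as_table(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    return ContingencyTable(np.asarray(table))


def _log_point_prob(counts: Sequence[Sequence[int]], row_m, col_m, n: int) -> float:
    """log multivariate hypergeometric probability of a table given its margins."""
    lp = (
        sum(math.lgamma(m + 1) for m in row_m)
        + sum(math.lgamma(m + 1) for m in col_m)
        - math.lgamma(n + 1)
    )
    lp -= sum(math.lgamma(x + 1) for row in counts for x in row)
    return lp


def _iter_tables_with_margins(row_m: list[int], col_m: list[int], max_tables: int) -> Iterator[list[list[int]]]:
    """All non-negative integer tables with the given margins.

    Recursive allocation row by row; within a row, cells are filled left to
    right bounded by the remaining column margins, so enumeration order is
    deterministic (lexicographic in the flattened table).
    """
    r, c = len(row_m), len(col_m)
    count = 0

    def fill_row(j: int, remaining: int, col_left: list[int], row: list[int]):
        if j == c - 1:
            if 0 <= remaining <= col_left[j]:
                yield row + [remaining]
            return
        tail_cap = sum(col_left[j + 1:])
        lo = max(0, remaining - tail_cap)
        hi = min(remaining, col_left[j])
        for v in range(lo, hi + 1):
            yield from fill_row(j + 1, remaining - v, col_left, row + [v])

    def rec(i: int, col_left: list[int], rows: list[list[int]]):
        nonlocal count
        if i == r - 1:
            count += 1
            if count > max_tables:
                raise EnumerationLimitError(
                    f"enumeration exceeds guard of {max_tables} tables"
                )
            yield rows + [list(col_left)]
            return
        for row in fill_row(0, row_m[i], col_left, []):
            new_left = [cl - v for cl, v in zip(col_left, row)]
            yield from rec(i + 1, new_left, rows + [row])

    yield from rec(0, list(col_m), [])


def freeman_halton_exact(table, *, max_tables: int = DEFAULT_MAX_TABLES) -> float:
    """Two-sided exact test for an r x c table (point-probability convention).

    Reduces exactly to :func:`fisher_exact_two_sided` on 2 x 2 input.
    """
    t = _as_table(table)
    t.require_positive_margins()
    row_m = t.row_margins.tolist()
    col_m = t.col_margins.tolist()
    n = t.n
    lp_obs = _log_point_prob(t.counts.tolist(), row_m, col_m, n)
    cutoff = lp_obs + math.log1p(TIE_RTOL)
    total = 0.0
    for cand in _iter_tables_with_margins(row_m, col_m, max_tables):
        lp = _log_point_prob(cand, row_m, col_m, n)
        if lp <= cutoff:
            total += math.exp(lp)
    return min(total, 1.0)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact test for a 2 x 2 table (point-probability convention)."""
    t = _as_table(table)
    if t.counts.shape != (2, 2):
        raise DomainError(f"fisher_exact_two_sided requires a 2x2 table, got {t.counts.shape}")
    t.require_positive_margins()
    # 2x2 enumeration is one-dimensional: the (0,0) cell determines the table
    row_m = t.row_margins.tolist()
    col_m = t.col_margins.tolist()
    n = t.n
    lp_obs = _log_point_prob(t.counts.tolist(), row_m, col_m, n)
    cutoff = lp_obs + math.log1p(TIE_RTOL)
    lo = max(0, row_m[0] - col_m[1])
    hi = min(row_m[0], col_m[0])
    total = 0.0
    for x in range(lo, hi + 1):
        cand = [[x, row_m[0] - x], [col_m[0] - x, row_m[1] - (col_m[0] - x)]]
        lp = _log_point_prob(cand, row_m, col_m, n)
        if lp <= cutoff:
            total += math.exp(lp)
    return min(total, 1.0)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p: float


def pearson_chi2(table, *, yates: bool = False) -> Chi2Result:
    """Pearson chi-squared test of independence (no continuity correction by default)."""
    t = _as_table(table)
    t.require_positive_margins()
    obs = t.counts.astype(float)
    expected = np.outer(t.row_margins, t.col_margins) / t.n
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return Chi2Result(statistic=stat, df=df, p=float(sps.chi2.sf(stat, df)))


@dataclass(frozen=True)
class GroupComparisonResult:
    method: str
    statistic: float
    p: float
    pairwise_p: dict[tuple, float] = field(default_factory=dict)


def compare_continuous_groups(
    values: Sequence[float],
    group_labels: Sequence,
    method: str,
) -> GroupComparisonResult:
    """Classical comparison of a continuous variable across groups.

    ``method``: ``t_test`` (two-tailed, two groups), ``mann_whitney`` (two
    groups, two-sided), ``kruskal_wallis_bonferroni`` (global Kruskal–Wallis
    plus pairwise Mann–Whitney p-values multiplied by the number of
    comparisons, capped at 1), or ``spearman`` (rank correlation between
    ``values`` and ``group_labels`` taken as a second quantitative variable).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if len(values) != len(labels):
        raise DomainError("values and group_labels must have equal length")

    if method == "spearman":
        x = np.asarray(group_labels, dtype=float)
        if np.all(values == values[0]) or np.all(x == x[0]):
            raise UndefinedStatisticError("Spearman correlation undefined for constant input")
        rho, p = sps.spearmanr(values, x)
        return GroupComparisonResult(method=method, statistic=float(rho), p=float(p))

    groups = [values[labels == g] for g in sorted(set(labels.tolist()), key=str)]
    names = sorted(set(labels.tolist()), key=str)
    if any(len(g) < 2 for g in groups):
        raise DomainError("each group needs at least 2 observations")

    if method == "t_test":
        if len(groups) != 2:
            raise DomainError("t_test requires exactly 2 groups")
        stat, p = sps.ttest_ind(groups[0], groups[1])
        return GroupComparisonResult(method=method, statistic=float(stat), p=float(p))
    if method == "mann_whitney":
        if len(groups) != 2:
            raise DomainError("mann_whitney requires exactly 2 groups")
        stat, p = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return GroupComparisonResult(method=method, statistic=float(stat), p=float(p))
    if method == "kruskal_wallis_bonferroni":
        if len(groups) < 2:
            raise DomainError("kruskal_wallis requires at least 2 groups")
        stat, p = sps.kruskal(*groups)
        pairs = {}
        k = len(groups) * (len(groups) - 1) // 2
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                _, pp = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
                pairs[(names[a], names[b])] = min(1.0, float(pp) * k)
        return GroupComparisonResult(method=method, statistic=float(stat), p=float(p), pairwise_p=pairs)
    raise DomainError(f"unknown method {method!r}")
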