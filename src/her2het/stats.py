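"""Exact 2x2 tests and multiple-testing helpers.

Thin, validated wrappers around scipy/statsmodels: two-tailed Fisher's exact
test (point-probability rule), the one-tailed hypergeometric
under-representation test used for mutual exclusivity, a Haldane-corrected
odds ratio, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "fisher_two_tailed",
    "fisher_one_tailed_under",
    "odds_ratio",
    "bh_adjust",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows = group, columns = trait."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers: {cells}")
        if sum(cells) == 0:
            raise ValueError("empty table")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def _as_table(t) -> ContingencyTable2x2:
    if isinstance(t, ContingencyTable2x2):
        return t
    arr = np.asarray(t)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    return ContingencyTable2x2(*(int(v) for v in arr.ravel()))


def fisher_two_tailed(t) -> float:
    """Exact two-sided p: sum of hypergeometric point probabilities <= the
    observed table's, over all tables with the same margins."""
    table = _as_table(t)
    return float(sps.fisher_exact(table.as_array, alternative="two-sided")[1])


def fisher_one_tailed_under(t) -> float:
    """P(X <= a) under the hypergeometric null with the table's margins.

    With ``a`` the co-occurrence count, small p indicates the two traits
    co-occur less often than chance (mutual exclusivity).
    """
    table = _as_table(t)
    n_total = table.a + table.b + table.c + table.d
    row1 = table.a + table.b
    col1 = table.a + table.c
    return float(sps.hypergeom.cdf(table.a, n_total, row1, col1))


def odds_ratio(t) -> float:
    """Sample odds ratio a*d / (b*c), with a 0.5 Haldane-Anscombe correction
    applied to every cell when any cell is zero."""
    table = _as_table(t)
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p, q <= 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
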