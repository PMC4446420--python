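"""Fisher exact tests, Benjamini-Hochberg adjustment and editing comparisons.

A comparison contrasts A/G counts at residue 34 between two groups —
precursor vs processed reads within one library, or control vs knockdown
libraries — one 2x2 table per tRNA type.  P-values are two-sided Fisher
exact; the paper's figures mark both increases and decreases, and sidedness
is configurable for callers who want a directional test.  The BH family is
the set of types tested in one comparison (the eight ANN types by default),
mirroring per-figure adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = groups, columns = bases (A, G)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EditingComparison:
    """One per-type comparison of A/G proportions between two groups."""

    type_key: str
    n_A_group_a: int
    n_G_group_a: int
    n_A_group_b: int
    n_G_group_b: int
    p_value: float
    q_value: float = float("nan")
    stars: str = "na"
    direction: str = "na"

    @property
    def fraction_a(self) -> float:
        n = self.n_A_group_a + self.n_G_group_a
        return self.n_G_group_a / n if n else float("nan")

    @property
    def fraction_b(self) -> float:
        n = self.n_A_group_b + self.n_G_group_b
        return self.n_G_group_b / n if n else float("nan")


def fisher_exact_2x2(table: ContingencyTable2x2, alternative: str = "two-sided") -> float:
    """Fisher exact p-value for a 2x2 table; NaN for the all-zero table.

    Two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's
    (ties included within a small relative tolerance, as is conventional).
    Degenerate (zero-margin) tables give p = 1.
    """
    if table.total == 0:
        return float("nan")
    _, p = sps.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative=alternative)
    return float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    Missing entries (NaN) propagate as NaN and are excluded from the family
    size m.  Each adjusted value is min over j >= rank of p_(j) * m / j,
    capped at 1, so q >= p element-wise and q is monotone in p.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    ps = p[mask]
    if ps.size == 0:
        return q
    if (ps < 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = ps.size
    order = np.argsort(ps, kind="mergesort")
    scaled = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    np.minimum(adj, 1.0, out=adj)
    out = np.empty(m)
    out[order] = adj
    # p*(m/j) at j=m can round one ulp below p; the step-up value is >= p exactly
    q[mask] = np.maximum(out, ps)
    return q


def stars_for(q: float) -> str:
    if np.isnan(q):
        return "na"
    for thr, label in STAR_THRESHOLDS:
        if q <= thr:
            return label
    return "ns"


def compare_editing(
    group_a: Mapping[str, tuple[int, int]],
    group_b: Mapping[str, tuple[int, int]],
    family: Sequence[str] | None = None,
    alternative: str = "two-sided",
) -> list[EditingComparison]:
    """Per-type Fisher tests of A/G proportions between two groups, BH-adjusted.

    ``group_a``/``group_b`` map type_key to ``(n_A, n_G)`` counts at residue
    34.  ``family`` fixes the tested family (default: sorted union of keys);
    a type missing from either group yields a comparison with missing p/q,
    excluded from the BH family size.  ``direction`` describes group B
    relative to group A ("increased"/"reduced"/"none").
    """
    if family is None:
        family = sorted(set(group_a) | set(group_b))
    comparisons: list[EditingComparison] = []
    for key in family:
        if key in group_a and key in group_b:
            (a_A, a_G), (b_A, b_G) = group_a[key], group_b[key]
            table = ContingencyTable2x2(a_A, a_G, b_A, b_G)
            p = fisher_exact_2x2(table, alternative=alternative)
        else:
            (a_A, a_G) = group_a.get(key, (0, 0))
            (b_A, b_G) = group_b.get(key, (0, 0))
            p = float("nan")
        comparisons.append(EditingComparison(key, a_A, a_G, b_A, b_G, p))
    qs = bh_adjust([c.p_value for c in comparisons])
    for c, q in zip(comparisons, qs):
        c.q_value = float(q)
        c.stars = stars_for(c.q_value)
        fa, fb = c.fraction_a, c.fraction_b
        if np.isnan(fa) or np.isnan(fb):
            c.direction = "na"
        elif fb > fa:
            c.direction = "increased"
        elif fb < fa:
            c.direction = "reduced"
        else:
            c.direction = "none"
    return comparisons


def comparisons_frame(comparisons: Iterable[EditingComparison]) -> pd.DataFrame:
    rows = [
        {
            "type_key": c.type_key,
            "n_A_group_a": c.n_A_group_a, "n_G_group_a": c.n_G_group_a,
            "n_A_group_b": c.n_A_group_b, "n_G_group_b": c.n_G_group_b,
            "fraction_a": c.fraction_a, "fraction_b": c.fraction_b,
            "p_value": c.p_value, "q_value": c.q_value,
            "stars": c.stars, "direction": c.direction,
        }
        for c in comparisons
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "type_key",
            "n_A_group_a", "n_G_group_a", "n_A_group_b", "n_G_group_b",
            "fraction_a", "fraction_b", "p_value", "q_value", "stars", "direction",
        ],
    )


def wilson_interval(n_success: int, n_total: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (convenience only)."""
    if n_total == 0:
        return (float("nan"), float("nan"))
    res = sps.binomtest(n_success, n_total).proportion_ci(confidence_level=confidence, method="wilson")
    return (float(res.low), float(res.high))
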