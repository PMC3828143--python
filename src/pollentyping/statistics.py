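"""Exact and asymptotic tests used in hotspot analyses.

Covers 2x2 Fisher exact tests (one- and two-tailed), binomial
CDF-inversion confidence intervals for event frequencies, the
left/right x orientation breakpoint asymmetry test, the Pearson
chi-square partition test, and rate ratios.

The confidence-interval convention deserves a note: both bounds invert the
binomial CDF *at the observed count k* — the lower bound solves
``P(X <= k) = (1+level)/2`` and the upper solves ``P(X <= k) = (1-level)/2``.
This differs slightly from the textbook Clopper-Pearson interval (which uses
``k-1`` in the lower-tail condition) and is the convention used throughout
this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .hotspot import BreakpointObservation, Orientation

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact",
    "binomial_ci_cdf_at_k",
    "leftright_orientation_test",
    "partition_chi2",
    "rate_ratio",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Four non-negative counts [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cells must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one positive margin required")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
    alternative: str = "two_tailed",
) -> float:
    """Fisher's exact test p-value for a 2x2 table.

    ``one_tailed_less`` is the lower tail in the top-left cell (probability
    of a table at least as extreme in the direction of fewer ``a`` counts);
    ``two_tailed`` sums the point probabilities of all tables with the same
    margins whose probability does not exceed the observed one.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(a, b, c, d)
    arr = table.as_array()
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        warnings.warn("empty margin: no association possible, p = 1", stacklevel=2)
        return 1.0
    alt = {"one_tailed_less": "less", "two_tailed": "two-sided"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(stats.fisher_exact(arr, alternative=alt).pvalue)


def binomial_ci_cdf_at_k(
    k: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed binomial CI by numerically inverting the CDF at k.

    The bounds are the proportions p at which the binomial distribution
    function evaluated at the observed count equals (1+level)/2 (lower) and
    (1-level)/2 (upper).  k = 0 gives lower = 0; k = n gives upper = 1.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    alpha = (1.0 - level) / 2.0

    def solve(target: float) -> float:
        fun = lambda p: stats.binom.cdf(k, n, p) - target
        return float(optimize.brentq(fun, 0.0, 1.0, xtol=1e-15, rtol=1e-14))

    if k == 0:
        lower = 0.0
    elif k == n:
        # F(n; n, p) = 1 for every p; the nearest condition P(X >= n) = alpha
        # gives the standard closed form
        lower = alpha ** (1.0 / n)
    else:
        lower = solve(1.0 - alpha)
    upper = 1.0 if k == n else solve(alpha)
    return lower, upper


def leftright_orientation_test(
    breakpoints: Sequence[BreakpointObservation], median_position: float
) -> tuple[ContingencyTable2x2, float]:
    """Two-tailed Fisher test of breakpoint side vs CO orientation.

    Breakpoint midpoints on each side of the given median position are
    counted separately for the two reciprocal orientations and the
    association of the resulting 2x2 table is tested.  Midpoints exactly at
    the median count as left.
    """
    counts = {(o, side): 0 for o in Orientation for side in ("left", "right")}
    for bp in breakpoints:
        side = "left" if bp.midpoint <= median_position else "right"
        counts[(bp.orientation, side)] += 1
    for o in Orientation:
        if counts[(o, "left")] + counts[(o, "right")] == 0:
            raise ValueError(f"no breakpoints in orientation {o.value}")
    table = ContingencyTable2x2(
        a=counts[(Orientation.P1toP2, "left")],
        b=counts[(Orientation.P1toP2, "right")],
        c=counts[(Orientation.P2toP1, "left")],
        d=counts[(Orientation.P2toP1, "right")],
    )
    return table, fisher_exact(table, "two_tailed")


def partition_chi2(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
    yates: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square (1 df) for a 2x2 partition of CO counts.

    No continuity correction by default; set ``yates=True`` to apply it.
    Returns (statistic, p-value).
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(a, b, c, d)
    arr = table.as_array().astype(float)
    expected = stats.contingency.expected_freq(arr)
    if np.any(expected <= 0):
        raise ValueError("zero expected cell count")
    res = stats.chi2_contingency(arr, correction=yates)
    return float(res.statistic), float(res.pvalue)


def rate_ratio(rate_a: float, rate_b: float, decimals: int | None = None) -> float:
    """Ratio of two rates, optionally rounded (0 decimals for fold changes)."""
    if rate_b <= 0:
        raise ValueError("denominator rate must be > 0")
    ratio = rate_a / rate_b
    return round(ratio, decimals) if decimals is not None else ratio
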