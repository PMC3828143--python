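"""Hotspot shape analysis: cM/Mb profiles, Gaussian fits, orientation asymmetry.

Crossover breakpoints are mapped to open intervals between flanking
polymorphisms.  With the locus crossover frequency F (a proportion of
gametes, from the Bayesian dilution estimate or user input), per-interval
rates are expressed in cM/Mb: the locus carries ``100 * F`` cM in total,
apportioned over inter-marker intervals by breakpoint-midpoint counts and
divided by interval length in Mb.

Hotspot shapes are fitted as Gaussians (or mixtures) by least squares
between observed per-interval breakpoint fractions and the theoretical
integrated (CDF-difference) Gaussian mass over each interval.  The reported
width95 = 3.92 * sigma is the span containing the central 95% of the fitted
normal.

Orientation asymmetry (the displacement between reciprocal-orientation
breakpoint distributions, a signature of preferential initiation on one
parental chromosome) is summarized by the difference of orientation-wise
mean breakpoint midpoints and by cumulative per-marker curves.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .haplotypes import MarkerMap

__all__ = [
    "Orientation",
    "BreakpointObservation",
    "IntervalRateProfile",
    "GaussianFit",
    "interval_rates",
    "fit_gaussian_mixture",
    "cumulative_curves",
    "orientation_separation",
    "median_breakpoint_position",
    "center_allele_proportion",
]

WIDTH95_FACTOR = 3.92  # central 95% mass of a normal spans 2*1.96 sigma


class Orientation(str, enum.Enum):
    """Reciprocal CO orientation: which parental haplotype comes first
    reading left to right (P1toP2 = 'CtoL' when P1 is Col)."""

    P1toP2 = "P1toP2"
    P2toP1 = "P2toP1"


@dataclass(frozen=True)
class BreakpointObservation:
    """A CO exchange localized to an open interval between marker positions."""

    orientation: Orientation
    left: int
    right: int
    molecule_id: str = ""

    def __post_init__(self) -> None:
        if not self.left < self.right:
            raise ValueError("breakpoint interval requires left < right")

    @property
    def midpoint(self) -> float:
        return (self.left + self.right) / 2.0


def _midpoints(breakpoints: Iterable[BreakpointObservation]) -> np.ndarray:
    return np.array([bp.midpoint for bp in breakpoints], dtype=float)


@dataclass(frozen=True)
class IntervalRateProfile:
    """Per inter-marker interval CO counts and rates in cM/Mb."""

    starts: np.ndarray  # bp, left marker of each interval
    ends: np.ndarray  # bp, right marker
    counts: np.ndarray
    rates_cM_Mb: np.ndarray
    n_total: int
    frequency: float  # locus CO frequency F, proportion

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n_total

    def total_cM(self) -> float:
        """Integral of the profile over the region, in cM."""
        return float(np.sum(self.rates_cM_Mb * self.lengths / 1e6))


def interval_rates(
    breakpoints: Sequence[BreakpointObservation],
    marker_map: MarkerMap,
    frequency: float,
) -> IntervalRateProfile:
    """Bin breakpoint midpoints into inter-marker intervals and convert to cM/Mb.

    ``rate_i = 100 * F * (n_i / n_total) / (L_i in Mb)`` so that the profile
    integrates back to the locus genetic length ``100 * F`` cM.
    """
    if len(breakpoints) < 1:
        raise ValueError("need at least one breakpoint")
    if not 0 < frequency < 1:
        raise ValueError("frequency must be a proportion in (0, 1)")
    pos = np.asarray(marker_map.positions, dtype=float)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("zero-length inter-marker interval")
    mids = _midpoints(breakpoints)
    # midpoints of open intervals between markers always fall strictly inside
    idx = np.searchsorted(pos, mids, side="right") - 1
    if np.any(idx < 0) or np.any(idx >= len(pos) - 1):
        raise ValueError("breakpoint midpoint outside the marker map span")
    counts = np.bincount(idx, minlength=len(pos) - 1).astype(float)
    n_total = len(breakpoints)
    lengths = np.diff(pos)
    rates = 100.0 * frequency * (counts / n_total) / (lengths / 1e6)
    return IntervalRateProfile(
        starts=pos[:-1],
        ends=pos[1:],
        counts=counts,
        rates_cM_Mb=rates,
        n_total=n_total,
        frequency=frequency,
    )


@dataclass(frozen=True)
class GaussianFit:
    """One fitted Gaussian component of a hotspot shape."""

    mu: float  # bp
    sigma: float  # bp
    weight: float
    sse: float
    converged: bool = True

    @property
    def width95(self) -> float:
        return WIDTH95_FACTOR * self.sigma


def _mixture_interval_mass(
    starts: np.ndarray, ends: np.ndarray, mus: np.ndarray, sigmas: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    mass = np.zeros_like(starts, dtype=float)
    for mu, s, w in zip(mus, sigmas, weights):
        mass += w * (stats.norm.cdf(ends, mu, s) - stats.norm.cdf(starts, mu, s))
    return mass


def _sse(profile: IntervalRateProfile, mus, sigmas, weights) -> float:
    pred = _mixture_interval_mass(
        profile.starts, profile.ends, np.asarray(mus), np.asarray(sigmas), np.asarray(weights)
    )
    return float(np.sum((profile.fractions - pred) ** 2))


def _unpack(theta: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mus = theta[:K]
    sigmas = np.exp(theta[K : 2 * K])
    if K == 1:
        weights = np.array([1.0])
    else:
        z = np.concatenate([theta[2 * K :], [0.0]])
        z = z - z.max()
        weights = np.exp(z) / np.exp(z).sum()
    return mus, sigmas, weights


def fit_gaussian_mixture(
    profile: IntervalRateProfile, K: int = 1, *, n_starts: int = 12, seed: int = 0
) -> list[GaussianFit]:
    """Least-squares Gaussian (mixture) fit of a binned hotspot shape.

    Minimizes the sum over inter-marker intervals of squared differences
    between observed breakpoint fractions and the mixture mass integrated
    over each interval.  Multi-start Nelder-Mead local optimization is
    seeded from moment estimates plus jittered restarts.

    Returns one :class:`GaussianFit` per component, sorted by mu.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    nonempty = int(np.sum(profile.counts > 0))
    if nonempty < 3 * K:
        raise ValueError(
            f"K={K} needs >= {3 * K} non-empty intervals, got {nonempty}"
        )
    rng = np.random.default_rng(seed)
    mids = (profile.starts + profile.ends) / 2
    frac = profile.fractions
    mean0 = float(np.sum(mids * frac))
    sd0 = float(np.sqrt(np.sum((mids - mean0) ** 2 * frac)))
    sd0 = max(sd0, np.min(profile.lengths) / 2)
    span = profile.ends[-1] - profile.starts[0]

    # moment-based start plus quantile-spread starts for mixtures
    starts = []
    if K == 1:
        starts.append(np.array([mean0, np.log(sd0)]))
    else:
        qs = np.linspace(0.15, 0.85, K)
        cum = np.concatenate([[0.0], np.cumsum(frac)])
        grid = np.concatenate([[profile.starts[0]], profile.ends])
        q_pos = np.interp(qs, cum / cum[-1], grid)
        starts.append(
            np.concatenate([q_pos, np.full(K, np.log(sd0 / K)), np.zeros(K - 1)])
        )
    base = starts[0]
    for _ in range(n_starts - 1):
        jitter = rng.normal(scale=0.15, size=base.shape)
        jitter[:K] = rng.normal(scale=span / 8, size=K)
        starts.append(base + jitter)

    def objective(theta: np.ndarray) -> float:
        mus, sigmas, weights = _unpack(theta, K)
        return _sse(profile, mus, sigmas, weights)

    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("Gaussian mixture optimization failed to converge")
    mus, sigmas, weights = _unpack(best.x, K)
    order = np.argsort(mus)
    return [
        GaussianFit(
            mu=float(mus[i]),
            sigma=float(sigmas[i]),
            weight=float(weights[i]),
            sse=float(best.fun),
            converged=bool(best.success),
        )
        for i in order
    ]


def cumulative_curves(
    breakpoints: Sequence[BreakpointObservation], marker_map: MarkerMap
) -> dict[Orientation, np.ndarray]:
    """Cumulative relative CO rate at each marker position, per orientation.

    For each orientation the curve value at marker j is the fraction of that
    orientation's breakpoints whose midpoint lies left of the marker; curves
    are nondecreasing and end at 1.
    """
    pos = np.asarray(marker_map.positions, dtype=float)
    out: dict[Orientation, np.ndarray] = {}
    for orient in Orientation:
        mids = _midpoints([bp for bp in breakpoints if bp.orientation is orient])
        if len(mids) == 0:
            continue
        out[orient] = np.searchsorted(np.sort(mids), pos, side="right") / len(mids)
    if not out:
        raise ValueError("need at least one breakpoint in some orientation")
    return out


def orientation_separation(breakpoints: Sequence[BreakpointObservation]) -> float:
    """Signed bp difference of mean breakpoint midpoints (P1toP2 - P2toP1)."""
    by = {o: _midpoints([bp for bp in breakpoints if bp.orientation is o]) for o in Orientation}
    for o, mids in by.items():
        if len(mids) == 0:
            raise ValueError(f"no breakpoints in orientation {o.value}")
    return float(by[Orientation.P1toP2].mean() - by[Orientation.P2toP1].mean())


def median_breakpoint_position(breakpoints: Sequence[BreakpointObservation]) -> float:
    """Median of breakpoint midpoints (linear interpolation between order stats)."""
    if len(breakpoints) == 0:
        raise ValueError("need at least one breakpoint")
    return float(np.median(_midpoints(breakpoints)))


def center_allele_proportion(
    breakpoints: Sequence[BreakpointObservation], position: float
) -> float:
    """Fraction of CO molecules carrying the first parent's allele at ``position``.

    A P1toP2 molecule carries P1 left of its exchange and P2 right of it, so
    it holds the P1 allele at ``position`` iff its breakpoint midpoint lies
    right of ``position`` (and conversely for P2toP1).  An excess over 0.5
    at the hotspot centre indicates over-transmission of the first parent's
    allele, the expected footprint of preferential initiation on the second
    parent's chromatid.
    """
    if len(breakpoints) == 0:
        raise ValueError("need at least one breakpoint")
    n_p1 = 0
    for bp in breakpoints:
        right_of = bp.midpoint > position
        carries_p1 = right_of if bp.orientation is Orientation.P1toP2 else not right_of
        n_p1 += carries_p1
    return n_p1 / len(breakpoints)
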