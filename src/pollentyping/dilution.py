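"""Poisson single-molecule PCR model and Bayesian rate inference.

Limiting-dilution PCR distributes template molecules over wells so that each
well holds on average less than one amplifiable target.  The number of
target molecules in a well is Poisson; a well is negative exactly when it
received zero amplifiable molecules, so the negative-well fraction estimates
the per-well mean ``m`` through the Poisson zero term ``e^-m``.

Two primer kinds probe the same DNA sample of unknown per-well concentration
``C`` (molecules per well, undiluted):

* PARENTAL primers amplify non-recombinant molecules of one parental
  haplotype; only a fraction ``f`` (default 1/2 — one of the two parental
  haplotypes) of the molecules is amplifiable, so at dilution ``D`` the
  probability a well is negative is ``exp(-f * C * D)``.
* RECOMBINANT primers amplify molecules recombinant in the assayed interval
  and of one orientation; with recombination rate ``r`` the negative-well
  probability is ``exp(-f * r * C * D)``.

Observed negative counts per plate are binomial, which gives an explicit
joint likelihood for ``(C, r)``.  With independent uniform priors (``r`` on
``[0, r_max]``, ``C`` on a positivity-constrained interval), the posterior
is evaluated on a 2-D grid (``C`` log-spaced, ``r`` linear) and summarized
by marginal means, modes, and equal-tailed 95% intervals.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "PrimerKind",
    "DilutionEntry",
    "DilutionSeries",
    "ModelParams",
    "PriorSpec",
    "PosteriorGrid",
    "RateEstimate",
    "neg_well_prob",
    "series_log_likelihood",
    "posterior_scan",
    "estimate",
    "quantify_by_poisson",
]

DEFAULT_AMPLIFIABLE_FRACTION = 0.5


class PrimerKind(str, enum.Enum):
    PARENTAL = "PARENTAL"
    RECOMBINANT = "RECOMBINANT"


@dataclass(frozen=True)
class DilutionEntry:
    """One plate: ``wells`` reactions at dilution ``dilution``, of which
    ``negatives`` produced no product."""

    dilution: float
    wells: int
    negatives: int

    def __post_init__(self) -> None:
        if not 0 < self.dilution <= 1:
            raise ValueError(f"dilution must be in (0, 1], got {self.dilution}")
        if self.wells < 1:
            raise ValueError("wells must be >= 1")
        if not 0 <= self.negatives <= self.wells:
            raise ValueError(
                f"negatives ({self.negatives}) must be in [0, wells={self.wells}]"
            )


@dataclass(frozen=True)
class DilutionSeries:
    """Plate observations for one primer-pair kind."""

    primer_kind: PrimerKind
    entries: tuple[DilutionEntry, ...]

    def __init__(self, primer_kind: PrimerKind | str, entries: Iterable[DilutionEntry]):
        object.__setattr__(self, "primer_kind", PrimerKind(primer_kind))
        object.__setattr__(self, "entries", tuple(entries))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def min_dilution(self) -> float:
        return min(e.dilution for e in self.entries)


@dataclass(frozen=True)
class ModelParams:
    """Model parameters: concentration C (molecules/well undiluted),
    recombination rate r, and amplifiable fraction f per primer pair."""

    C: float
    r: float = 0.0
    f: float = DEFAULT_AMPLIFIABLE_FRACTION

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if not 0 <= self.r <= 1:
            raise ValueError("r must be in [0, 1]")
        if not 0 < self.f <= 1:
            raise ValueError("f must be in (0, 1]")


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors for r and C.

    ``r`` is uniform on ``[0, r_max]``.  ``C`` is uniform on
    ``[C_lo, C_hi]``; when bounds are not given they are derived from the
    parental series so that at least 10% positive reactions are expected at
    the most dilute plate (lower bound) and at most 99.9% positives
    (upper bound).
    """

    r_max: float = 0.1
    C_lo: float | None = None
    C_hi: float | None = None

    def resolve_C_bounds(
        self, parental: DilutionSeries, f: float
    ) -> tuple[float, float]:
        d_min = parental.min_dilution
        lo = self.C_lo if self.C_lo is not None else -math.log(0.9) / (f * d_min)
        hi = self.C_hi if self.C_hi is not None else -math.log(1e-3) / (f * d_min)
        if not 0 < lo < hi:
            raise ValueError(f"invalid C prior bounds [{lo}, {hi}]")
        return lo, hi


def neg_well_prob(params: ModelParams, dilution: float, kind: PrimerKind | str) -> float:
    """Probability that a single well yields no amplification.

    Poisson zero term: ``exp(-f*C*D)`` for parental primers,
    ``exp(-f*r*C*D)`` for recombinant primers.
    """
    if dilution <= 0:
        raise ValueError("dilution must be > 0")
    kind = PrimerKind(kind)
    lam = params.f * params.C * dilution
    if kind is PrimerKind.RECOMBINANT:
        lam *= params.r
    return math.exp(-lam)


def _binom_logpmf(y: np.ndarray | int, n: np.ndarray | int, logp: np.ndarray) -> np.ndarray:
    """log C(n,y) + y*log p + (n-y)*log(1-p) with p given as log p.

    Stable for p extremely close to 0 or 1 (log1p(-exp(logp)) handles the
    complement).  y == 0 and y == n edge terms are handled exactly.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    logp = np.asarray(logp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log1mp = np.where(logp < 0, np.log(-np.expm1(logp)), -np.inf)
    coef = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    term_p = np.where(y > 0, y * logp, 0.0)
    term_q = np.where(n - y > 0, (n - y) * log1mp, 0.0)
    return coef + term_p + term_q


def series_log_likelihood(series: DilutionSeries, params: ModelParams) -> float:
    """Joint log-likelihood of all plates of one primer kind.

    Each plate contributes a binomial term for its negative-well count with
    per-well negative probability from :func:`neg_well_prob`.
    """
    total = 0.0
    for e in series.entries:
        lam = params.f * params.C * e.dilution
        if series.primer_kind is PrimerKind.RECOMBINANT:
            lam *= params.r
        total += float(_binom_logpmf(e.negatives, e.wells, -lam))
    return total


@dataclass
class PosteriorGrid:
    """Discretized joint posterior over (C, r).

    ``joint`` holds normalized probability masses on the C x r grid
    (trapezoid cell weights, so piecewise-linear densities integrate
    exactly); marginals are consistent row/column sums.
    """

    C_grid: np.ndarray
    r_grid: np.ndarray
    joint: np.ndarray
    log_norm: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if abs(self.joint.sum() - 1.0) > 1e-9:
            raise ValueError("joint posterior masses must sum to 1")

    @property
    def C_marginal(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def r_marginal(self) -> np.ndarray:
        return self.joint.sum(axis=0)

    def marginal(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        if which == "C":
            return self.C_grid, self.C_marginal
        if which == "r":
            return self.r_grid, self.r_marginal
        raise ValueError("which must be 'C' or 'r'")


@dataclass(frozen=True)
class RateEstimate:
    """Marginal posterior summary: mean, mode and equal-tailed 95% interval."""

    mean: float
    mode: float
    lower: float
    upper: float
    level: float = 0.95


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.zeros_like(grid)
    w[1:] += np.diff(grid) / 2
    w[:-1] += np.diff(grid) / 2
    return w


def posterior_scan(
    parental: DilutionSeries,
    recombinant: DilutionSeries | None,
    prior: PriorSpec | None = None,
    *,
    f: float = DEFAULT_AMPLIFIABLE_FRACTION,
    n_C: int = 200,
    n_r: int = 200,
) -> PosteriorGrid:
    """Two-dimensional scan of the (C, r) parameter space.

    The posterior is proportional to the joint binomial likelihood of both
    series times the independent uniform priors, evaluated on a log-spaced C
    grid and linear r grid and normalized in log space.

    With no recombinant data the r marginal reproduces the uniform prior.

    Raises
    ------
    ValueError
        If the likelihood underflows to zero over the whole prior support
        (data incompatible with the prior bounds).
    """
    if prior is None:
        prior = PriorSpec()
    if len(parental) == 0:
        raise ValueError("parental series must be non-empty")
    if n_C < 50 or n_r < 50:
        raise ValueError("grid resolution must be >= 50 per axis")
    C_lo, C_hi = prior.resolve_C_bounds(parental, f)
    C_grid = np.geomspace(C_lo, C_hi, n_C)
    r_grid = np.linspace(0.0, prior.r_max, n_r)

    # log-likelihood over the grid; C varies along axis 0, r along axis 1
    logL = np.zeros((n_C, n_r))
    for e in parental.entries:
        lam = f * C_grid * e.dilution  # (n_C,)
        logL += _binom_logpmf(e.negatives, e.wells, -lam)[:, None]
    if recombinant is not None and len(recombinant) > 0:
        for e in recombinant.entries:
            lam = f * np.outer(C_grid, r_grid) * e.dilution  # (n_C, n_r)
            logL += _binom_logpmf(e.negatives, e.wells, -lam)

    # uniform priors are flat over the grid: they drop out after normalization
    w = np.outer(_trapezoid_weights(C_grid), _trapezoid_weights(r_grid))
    log_mass = logL + np.log(w)
    log_norm = float(logsumexp(log_mass))
    if not np.isfinite(log_norm):
        raise ValueError(
            "zero posterior mass on the whole grid: data incompatible with "
            f"prior support C in [{C_lo:.3g}, {C_hi:.3g}], r in [0, {prior.r_max}]"
        )
    joint = np.exp(log_mass - log_norm)
    joint /= joint.sum()
    # a posterior pinched against a C prior bound means the prior support
    # excludes the likelihood peak
    c_marg = joint.sum(axis=1)
    if c_marg[0] > 0.5:
        raise ValueError(
            f"posterior mass piles up at the C prior lower bound C_lo={C_lo:.4g}; "
            "lower it or check the plate data"
        )
    if c_marg[-1] > 0.5:
        raise ValueError(
            f"posterior mass piles up at the C prior upper bound C_hi={C_hi:.4g}; "
            "raise it or check the plate data"
        )
    return PosteriorGrid(C_grid=C_grid, r_grid=r_grid, joint=joint, log_norm=log_norm)


def _quantile_from_masses(grid: np.ndarray, masses: np.ndarray, q: float) -> float:
    """Quantile of a piecewise-linear density reconstructed from node masses.

    Node masses are converted back to densities via trapezoid weights; the
    CDF at the nodes is then the exact integral of the piecewise-linear
    density, and the quantile is found by inverting a linear interpolation
    of that CDF (exact for locally uniform marginals).
    """
    w = _trapezoid_weights(grid)
    dens = masses / w
    seg = (dens[:-1] + dens[1:]) / 2 * np.diff(grid)
    cdf = np.concatenate([[0.0], np.cumsum(seg)])
    cdf /= cdf[-1]
    return float(np.interp(q, cdf, grid))


def estimate(posterior: PosteriorGrid, which: str, level: float = 0.95) -> RateEstimate:
    """Marginal summary for C or r: posterior mean, mode, equal-tailed CI."""
    grid, masses = posterior.marginal(which)
    mean = float(np.sum(grid * masses))
    mode = float(grid[int(np.argmax(masses / _trapezoid_weights(grid)))])
    alpha = (1.0 - level) / 2.0
    lower = _quantile_from_masses(grid, masses, alpha)
    upper = _quantile_from_masses(grid, masses, 1.0 - alpha)
    return RateEstimate(mean=mean, mode=mode, lower=lower, upper=upper, level=level)


@dataclass(frozen=True)
class PoissonQuantification:
    """e^-m quantification result."""

    m: float
    undiluted_count: float


def quantify_by_poisson(
    wells: int, negatives: int, dilution: float, f: float = DEFAULT_AMPLIFIABLE_FRACTION
) -> PoissonQuantification:
    """Most-probable-number quantification from the negative-well fraction.

    The negative fraction approximates ``e^-m`` with ``m`` the mean number
    of amplifiable molecules per well, so ``m = -ln(y/N)``; the undiluted
    per-well concentration is ``m / (f * D)``.

    Raises
    ------
    ValueError
        If every well is positive (m is unbounded: dilute further).
    """
    if not 0 < dilution <= 1:
        raise ValueError("dilution must be in (0, 1]")
    if wells < 1 or not 0 <= negatives <= wells:
        raise ValueError("need 0 <= negatives <= wells, wells >= 1")
    if negatives == 0:
        raise ValueError(
            "all wells positive: m is unbounded, dilute further and repeat"
        )
    if negatives == wells:
        warnings.warn(
            "all wells negative: estimated m = 0 (no template detected)",
            stacklevel=2,
        )
    m = -math.log(negatives / wells)
    return PoissonQuantification(m=m, undiluted_count=m / (f * dilution))
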