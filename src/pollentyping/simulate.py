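"""Synthetic pollen-typing data with the statistical structure the analysis assumes.

Three generators emulate the wet-lab experiments:

* dilution plates — each well receives a Poisson number of amplifiable
  template molecules (mean ``f*C*D`` for parental primers, ``f*r*C*D`` for
  recombinant primers) and is negative iff it received none;
* CO breakpoints — true exchange points drawn from a Gaussian mixture over
  the region, with the two reciprocal orientations' component means offset
  symmetrically by ±delta/2 (the signature of biased initiation), truncated
  to the marker span by resampling, and observed only as the flanking-marker
  interval;
* NCO events — initiation sites drawn from the same kind of mixture, a
  conversion tract of sampled length placed over the initiation site, and
  the event *detected* only if a designated assay SNP lies inside the tract
  (the ascertainment that makes observed NCO counts undercount initiation).

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .dilution import DilutionEntry, DilutionSeries, PrimerKind
from .haplotypes import MarkerMap
from .hotspot import BreakpointObservation, Orientation
from .nco import NCOEvent

__all__ = [
    "GaussianComponent",
    "PlateDesign",
    "SimulationConfig",
    "TrueNCO",
    "simulate_plates",
    "simulate_breakpoints",
    "simulate_nco_events",
]


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian hotspot component: centre mu (bp), sd sigma (bp), weight."""

    mu: float
    sigma: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


@dataclass(frozen=True)
class PlateDesign:
    """One plate to simulate: primer kind, dilution D, number of wells N."""

    primer_kind: PrimerKind
    dilution: float
    wells: int


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror the study conditions of a strong A. thaliana hotspot
    assay: ~2000 molecules per undiluted well, CO rate r = 0.55%, hotspot
    sd ~376 bp, orientation offset 213 bp, initiation biased to the second
    parent (beta = 0.8), and short geometric conversion tracts (mean 150 bp).
    """

    marker_map: MarkerMap
    seed: int = 0
    C: float = 2000.0
    r: float = 0.0055
    f: float = 0.5
    plate_design: tuple[PlateDesign, ...] = ()
    components: tuple[GaussianComponent, ...] = ()
    orientation_offset: float = 213.0  # delta, bp
    initiation_bias: float = 0.8  # beta: P(initiation on the P2 chromatid)
    nco_initiation_rate: float = 0.005  # per genome
    tract_mean: float = 150.0  # mean tract length tau, bp
    tract_model: Literal["geometric", "fixed"] = "geometric"
    tract_placement: Literal["uniform", "left"] = "uniform"

    def __post_init__(self) -> None:
        if not 0 < self.r <= 0.1:
            raise ValueError("r must be in (0, 0.1]")
        if not 0 <= self.initiation_bias <= 1:
            raise ValueError("initiation_bias must be in [0, 1]")
        if self.tract_mean < 1:
            raise ValueError("tract_mean must be >= 1")
        total = sum(c.weight for c in self.components) if self.components else 1.0
        if self.components and abs(total - 1.0) > 1e-9:
            # renormalize weights so downstream mixtures sum to 1
            self.components = tuple(
                GaussianComponent(c.mu, c.sigma, c.weight / total)
                for c in self.components
            )

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def default_plate_design(r: float = 0.0055) -> tuple[PlateDesign, ...]:
    """Three-dilution, 96-well design for each primer kind.

    Parental plates span dilutions around the single-molecule regime for the
    full template concentration; recombinant plates are ~1/r less dilute so
    that both assays sit near ~50% negative wells where the Poisson assay is
    most informative.
    """
    par = [PlateDesign(PrimerKind.PARENTAL, d, 96) for d in (2e-4, 7e-4, 2.4e-3)]
    rec = [
        PlateDesign(PrimerKind.RECOMBINANT, min(1.0, d / r), 96)
        for d in (2e-4, 7e-4, 2.4e-3)
    ]
    return tuple(par + rec)


def simulate_plates(
    config: SimulationConfig,
) -> tuple[DilutionSeries, DilutionSeries]:
    """Simulate negative-well counts for every plate in the design.

    Per well the amplifiable-template count is Poisson with mean ``f*C*D``
    (parental) or ``f*r*C*D`` (recombinant); the well is negative iff the
    count is zero.  Returns (parental series, recombinant series).
    """
    design = config.plate_design or default_plate_design(config.r)
    rng = config.rng(salt=1)
    entries: dict[PrimerKind, list[DilutionEntry]] = {k: [] for k in PrimerKind}
    for plate in design:
        lam = config.f * config.C * plate.dilution
        if plate.primer_kind is PrimerKind.RECOMBINANT:
            lam *= config.r
        counts = rng.poisson(lam, size=plate.wells)
        entries[plate.primer_kind].append(
            DilutionEntry(
                dilution=plate.dilution,
                wells=plate.wells,
                negatives=int(np.sum(counts == 0)),
            )
        )
    return (
        DilutionSeries(PrimerKind.PARENTAL, entries[PrimerKind.PARENTAL]),
        DilutionSeries(PrimerKind.RECOMBINANT, entries[PrimerKind.RECOMBINANT]),
    )


def _default_components(marker_map: MarkerMap) -> tuple[GaussianComponent, ...]:
    centre = (marker_map.positions[0] + marker_map.positions[-1]) / 2
    return (GaussianComponent(mu=centre, sigma=376.0, weight=1.0),)


def _sample_mixture(
    rng: np.random.Generator,
    components: Sequence[GaussianComponent],
    n: int,
    shift: np.ndarray | float,
    lo: float,
    hi: float,
    max_iter: int = 1000,
) -> np.ndarray:
    """Draw from a shifted Gaussian mixture truncated to (lo, hi) by resampling."""
    weights = np.array([c.weight for c in components])
    mus = np.array([c.mu for c in components])
    sigmas = np.array([c.sigma for c in components])
    comp = rng.choice(len(components), size=n, p=weights / weights.sum())
    x = rng.normal(mus[comp] + shift, sigmas[comp])
    for _ in range(max_iter):
        bad = (x <= lo) | (x >= hi)
        if not bad.any():
            break
        comp_bad = rng.choice(len(components), size=int(bad.sum()), p=weights / weights.sum())
        shift_bad = shift[bad] if isinstance(shift, np.ndarray) else shift
        x[bad] = rng.normal(mus[comp_bad] + shift_bad, sigmas[comp_bad])
    else:
        raise RuntimeError("truncation resampling did not converge; check region bounds")
    return x


@dataclass(frozen=True)
class SimulatedBreakpoint:
    """Observed flanking-marker interval plus the latent true position."""

    observation: BreakpointObservation
    true_position: float


def simulate_breakpoints(n: int, config: SimulationConfig) -> list[SimulatedBreakpoint]:
    """Draw n CO breakpoints and report them at marker resolution.

    True positions follow the configured Gaussian mixture; orientation is
    P2toP1 with probability ``initiation_bias``, and per-orientation means
    are offset by ±delta/2 (P1toP2 right, P2toP1 left — initiation on the
    second parent pulls its conversion-orientation exchanges leftward).
    Positions outside the marker span are resampled (truncation).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    components = config.components or _default_components(config.marker_map)
    rng = config.rng(salt=2)
    pos = np.asarray(config.marker_map.positions, dtype=float)
    is_p2 = rng.random(n) < config.initiation_bias
    shift = np.where(is_p2, -config.orientation_offset / 2, +config.orientation_offset / 2)
    x = _sample_mixture(rng, components, n, shift, pos[0], pos[-1])
    idx = np.searchsorted(pos, x, side="right") - 1
    out = []
    for i in range(n):
        orient = Orientation.P2toP1 if is_p2[i] else Orientation.P1toP2
        out.append(
            SimulatedBreakpoint(
                observation=BreakpointObservation(
                    orientation=orient,
                    left=int(pos[idx[i]]),
                    right=int(pos[idx[i] + 1]),
                    molecule_id=f"sim_co_{i}",
                ),
                true_position=float(x[i]),
            )
        )
    return out


@dataclass(frozen=True)
class TrueNCO:
    """Truth-log record of one initiated conversion event."""

    genome_index: int
    initiation: float
    tract_start: float
    tract_end: float
    orientation: str
    converted_marker_ids: tuple[str, ...]
    detected: bool


def simulate_nco_events(
    n_genomes: int,
    config: SimulationConfig,
    assay_marker_ids: Sequence[str] | None = None,
) -> tuple[list[NCOEvent], list[TrueNCO]]:
    """Simulate NCO initiation, conversion tracts, and assay ascertainment.

    Each genome initiates a conversion with probability
    ``nco_initiation_rate``; the initiation site follows the configured
    mixture, the tract length the configured model (geometric with mean
    ``tract_mean`` or fixed), and the tract is placed covering the
    initiation site (uniform placement by default).  Markers inside the
    tract are converted.  An event is *detected* iff one of the designated
    assay markers is converted; returns (detected events, full truth log).
    """
    components = config.components or _default_components(config.marker_map)
    rng = config.rng(salt=3)
    mmap = config.marker_map
    pos = np.asarray(mmap.positions, dtype=float)
    if assay_marker_ids is None:
        assay_marker_ids = (mmap.ids[len(mmap) // 2],)
    assay_idx = np.array([mmap.index_of(m) for m in assay_marker_ids])

    n_events = rng.binomial(n_genomes, config.nco_initiation_rate)
    init = _sample_mixture(
        rng, components, n_events, 0.0, mmap.start, mmap.end
    )
    if config.tract_model == "geometric":
        # support >= 1 bp; mean tau
        p = 1.0 / config.tract_mean
        lengths = rng.geometric(p, size=n_events).astype(float)
    else:
        lengths = np.full(n_events, config.tract_mean)
    if config.tract_placement == "uniform":
        offset = rng.random(n_events) * lengths
    else:
        offset = np.zeros(n_events)
    starts = init - offset
    ends = starts + lengths
    is_p2 = rng.random(n_events) < config.initiation_bias

    detected: list[NCOEvent] = []
    truth: list[TrueNCO] = []
    for i in range(n_events):
        inside = (pos >= starts[i]) & (pos <= ends[i])
        converted = tuple(mmap.ids[j] for j in np.nonzero(inside)[0])
        hit = bool(inside[assay_idx].any())
        orient = "P2toP1toP2" if is_p2[i] else "P1toP2toP1"
        truth.append(
            TrueNCO(
                genome_index=i,
                initiation=float(init[i]),
                tract_start=float(starts[i]),
                tract_end=float(ends[i]),
                orientation=orient,
                converted_marker_ids=converted,
                detected=hit and len(converted) > 0,
            )
        )
        if hit and converted:
            detected.append(
                NCOEvent(
                    molecule_id=f"sim_nco_{i}",
                    converted_marker_ids=converted,
                    orientation=orient,
                    chimeric=False,
                )
            )
    return detected, truth
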