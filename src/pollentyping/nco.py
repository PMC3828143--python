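"""Non-crossover (gene conversion) tract summarization.

An NCO is observed as a molecule whose haplotype switches to the other
parent over one or more markers and then switches back.  The true conversion
tract is only bracketed by the assayed polymorphisms:

* minimum tract = span of the converted markers (1 bp for a single marker),
* maximum tract = distance between the nearest non-converted flanking
  markers (the tract could extend to just before either flank),
* mid tract = the arithmetic mean of the two.

Per-SNP NCO frequencies are event counts over assayed genomes with
binomial CDF-inversion confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .haplotypes import MarkerMap
from .statistics import binomial_ci_cdf_at_k

__all__ = [
    "NCOEvent",
    "TractEstimate",
    "TractSummary",
    "NCOFrequency",
    "tract_bounds",
    "summarize_tracts",
    "nco_frequency",
]


@dataclass(frozen=True)
class NCOEvent:
    """A detected conversion event: the converted markers of one molecule.

    ``converted_marker_ids`` may be discontinuous for chimeric events
    (more than two haplotype transitions); those are flagged and summarized
    by their outermost converted markers only.
    ``orientation`` names the restored outer haplotype first, e.g.
    ``P1toP2toP1`` is a P1 molecule with a converted P2 patch.
    """

    molecule_id: str
    converted_marker_ids: tuple[str, ...]
    orientation: str = "P1toP2toP1"
    chimeric: bool = False

    def __post_init__(self) -> None:
        if len(self.converted_marker_ids) == 0:
            raise ValueError("an NCO event needs at least one converted marker")


@dataclass(frozen=True)
class TractEstimate:
    """Min/max/mid conversion-tract length bounds in bp.

    ``left_unbounded`` / ``right_unbounded`` flag events whose converted
    markers reach the map edge, leaving the maximum tract unbounded on that
    side (such events are excluded from tract means).
    """

    min_bp: int
    max_bp: int
    left_unbounded: bool = False
    right_unbounded: bool = False

    @property
    def bounded(self) -> bool:
        return not (self.left_unbounded or self.right_unbounded)

    @property
    def mid_bp(self) -> float:
        return (self.min_bp + self.max_bp) / 2.0


def tract_bounds(event: NCOEvent, marker_map: MarkerMap) -> TractEstimate:
    """Bracket the conversion tract of one event.

    min = rightmost converted position - leftmost converted position + 1;
    max = right flanking marker position - left flanking marker position
    (the tract ends just before each non-converted flank).
    """
    idx = sorted(marker_map.index_of(mid) for mid in event.converted_marker_ids)
    lo, hi = idx[0], idx[-1]
    pos = marker_map.positions
    min_bp = pos[hi] - pos[lo] + 1
    left_unbounded = lo == 0
    right_unbounded = hi == len(marker_map) - 1
    left_flank = pos[lo - 1] if not left_unbounded else marker_map.start
    right_flank = pos[hi + 1] if not right_unbounded else marker_map.end
    return TractEstimate(
        min_bp=int(min_bp),
        max_bp=int(right_flank - left_flank),
        left_unbounded=left_unbounded,
        right_unbounded=right_unbounded,
    )


@dataclass(frozen=True)
class TractSummary:
    """Tract-length means over a set of events."""

    n_events: int
    n_unbounded: int
    mean_min_bp: float
    mean_max_bp: float
    averaged_mid_bp: float  # (mean min + mean max) / 2

    def rounded(self) -> tuple[int, int, int]:
        """Means rounded to the nearest integer bp."""
        return (
            round(self.mean_min_bp),
            round(self.mean_max_bp),
            round(self.averaged_mid_bp),
        )


def summarize_tracts(tracts: Sequence[TractEstimate]) -> TractSummary:
    """Arithmetic means of min and max tract lengths over bounded events."""
    bounded = [t for t in tracts if t.bounded]
    n_unbounded = len(tracts) - len(bounded)
    if not bounded:
        raise ValueError("no events with bounded tracts")
    if n_unbounded:
        import warnings

        warnings.warn(
            f"{n_unbounded} event(s) with unbounded tracts excluded from means",
            stacklevel=2,
        )
    mean_min = sum(t.min_bp for t in bounded) / len(bounded)
    mean_max = sum(t.max_bp for t in bounded) / len(bounded)
    return TractSummary(
        n_events=len(bounded),
        n_unbounded=n_unbounded,
        mean_min_bp=mean_min,
        mean_max_bp=mean_max,
        averaged_mid_bp=(mean_min + mean_max) / 2.0,
    )


@dataclass(frozen=True)
class NCOFrequency:
    """NCO rate (proportion per genome) with its 95% CI."""

    n_events: int
    n_genomes: int
    rate: float
    ci_lower: float
    ci_upper: float

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.rate


def nco_frequency(n_events: int, n_genomes: int, level: float = 0.95) -> NCOFrequency:
    """Per-genome NCO frequency with a binomial CDF-inversion CI."""
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if not 0 <= n_events <= n_genomes:
        raise ValueError("need 0 <= n_events <= n_genomes")
    lower, upper = binomial_ci_cdf_at_k(n_events, n_genomes, level=level)
    return NCOFrequency(
        n_events=n_events,
        n_genomes=n_genomes,
        rate=n_events / n_genomes,
        ci_lower=lower,
        ci_upper=upper,
    )
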