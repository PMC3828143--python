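"""Marker maps and recombinant-molecule classification.

A pollen-typing assay genotypes single DNA molecules from an F1 hybrid at an
ordered set of polymorphisms (SNPs and small indels) spanning a hotspot
region.  Each molecule yields a vector of parental-origin calls (P1 = first
parent, e.g. Col; P2 = second parent, e.g. Ler) from which the molecule is
classified:

* 0 haplotype transitions  -> parental (non-recombinant),
* 1 transition             -> crossover (CO), with the exchange localized to
  the interval between the two flanking informative markers,
* 2 transitions restoring the outer haplotype -> non-crossover (NCO)
  gene conversion,
* more than 2 transitions  -> chimeric (discontinuous) conversion.

Coordinates are 1-based inclusive base pairs on the region's local reference.
Exchange intervals are open intervals between the flanking marker positions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "Call",
    "Category",
    "Marker",
    "MarkerMap",
    "MoleculeGenotype",
    "ClassifiedMolecule",
    "classify_molecule",
    "exchange_interval",
]


class Call(str, enum.Enum):
    """Parental-origin call at one marker."""

    P1 = "P1"
    P2 = "P2"
    MISSING = "NA"


class Category(str, enum.Enum):
    """Molecule category by number and pattern of haplotype transitions."""

    PARENTAL_P1 = "PARENTAL_P1"
    PARENTAL_P2 = "PARENTAL_P2"
    CO_P1toP2 = "CO_P1toP2"
    CO_P2toP1 = "CO_P2toP1"
    NCO_P1toP2toP1 = "NCO_P1toP2toP1"
    NCO_P2toP1toP2 = "NCO_P2toP1toP2"
    CHIMERIC = "CHIMERIC"

    @property
    def is_co(self) -> bool:
        return self in (Category.CO_P1toP2, Category.CO_P2toP1)

    @property
    def is_nco(self) -> bool:
        return self in (Category.NCO_P1toP2toP1, Category.NCO_P2toP1toP2)

    @property
    def is_parental(self) -> bool:
        return self in (Category.PARENTAL_P1, Category.PARENTAL_P2)


@dataclass(frozen=True)
class Marker:
    """A single polymorphism of the region.

    Indels are represented as point markers at their left-most reference
    coordinate; ``indel_size`` is 0 for a SNP.
    """

    id: str
    position: int
    allele_p1: str
    allele_p2: str
    indel_size: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"marker {self.id}: position must be >= 1")
        if self.allele_p1 == self.allele_p2:
            raise ValueError(f"marker {self.id}: parental alleles must differ")
        if self.indel_size < 0:
            raise ValueError(f"marker {self.id}: indel_size must be >= 0")


@dataclass(frozen=True)
class MarkerMap:
    """Ordered polymorphisms of a hotspot region.

    Positions must be strictly increasing and fall inside ``[start, end]``;
    marker ids must be unique.
    """

    region: str
    markers: tuple[Marker, ...]
    start: int
    end: int

    def __init__(self, region: str, markers: Sequence[Marker], start: int | None = None, end: int | None = None):
        markers = tuple(markers)
        if len(markers) < 2:
            raise ValueError("a marker map needs at least 2 markers")
        pos = [m.position for m in markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("marker positions must be strictly increasing")
        ids = [m.id for m in markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids must be unique")
        if start is None:
            start = pos[0]
        if end is None:
            end = pos[-1]
        if pos[0] < start or pos[-1] > end:
            raise ValueError("marker positions must lie within [start, end]")
        object.__setattr__(self, "region", region)
        object.__setattr__(self, "markers", markers)
        object.__setattr__(self, "start", int(start))
        object.__setattr__(self, "end", int(end))

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(m.position for m in self.markers)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.markers)

    def index_of(self, marker_id: str) -> int:
        try:
            return self.ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def intervals(self) -> list[tuple[int, int]]:
        """Inter-marker intervals as (left position, right position) pairs."""
        pos = self.positions
        return list(zip(pos, pos[1:]))


@dataclass(frozen=True)
class MoleculeGenotype:
    """Per-marker parental-origin calls for one sequenced molecule."""

    molecule_id: str
    calls: tuple[Call, ...]

    def __init__(self, molecule_id: str, calls: Sequence[Call | str]):
        calls = tuple(Call(c) for c in calls)
        n_informative = sum(1 for c in calls if c is not Call.MISSING)
        if n_informative < 2:
            raise ValueError(
                f"molecule {molecule_id}: needs >= 2 non-missing calls, got {n_informative}"
            )
        object.__setattr__(self, "molecule_id", molecule_id)
        object.__setattr__(self, "calls", calls)


@dataclass(frozen=True)
class ClassifiedMolecule:
    """Classification outcome with exchange-interval localization.

    ``transition_intervals`` holds (left marker id, right marker id) pairs:
    the nearest non-missing markers of different parental origin bracketing
    each haplotype transition.
    """

    molecule_id: str
    category: Category
    transition_intervals: tuple[tuple[str, str], ...]
    converted_marker_ids: tuple[str, ...] = field(default=())

    @property
    def n_transitions(self) -> int:
        return len(self.transition_intervals)


def classify_molecule(genotype: MoleculeGenotype, marker_map: MarkerMap) -> ClassifiedMolecule:
    """Classify a molecule into parental / CO / NCO / chimeric.

    Missing calls are transparently skipped: a transition is judged between
    the nearest non-missing neighbours, so sequencing gaps never create
    spurious transitions.  Molecules with a CO and an independent conversion
    (3+ transitions) are labelled chimeric.

    Raises
    ------
    ValueError
        If the call vector length does not match the map.
    """
    if len(genotype.calls) != len(marker_map):
        raise ValueError(
            f"molecule {genotype.molecule_id}: {len(genotype.calls)} calls for "
            f"{len(marker_map)} markers"
        )
    informative = [
        (i, c) for i, c in enumerate(genotype.calls) if c is not Call.MISSING
    ]
    transitions: list[tuple[str, str]] = []
    for (i, a), (j, b) in zip(informative, informative[1:]):
        if a is not b:
            transitions.append((marker_map.markers[i].id, marker_map.markers[j].id))

    first = informative[0][1]
    n = len(transitions)
    converted: tuple[str, ...] = ()
    if n == 0:
        cat = Category.PARENTAL_P1 if first is Call.P1 else Category.PARENTAL_P2
    elif n == 1:
        cat = Category.CO_P1toP2 if first is Call.P1 else Category.CO_P2toP1
    elif n == 2:
        # two transitions always restore the outer haplotype
        cat = (
            Category.NCO_P1toP2toP1 if first is Call.P1 else Category.NCO_P2toP1toP2
        )
        converted = _converted_ids(informative, first, marker_map)
    else:
        cat = Category.CHIMERIC
        converted = _converted_ids(informative, first, marker_map)
    return ClassifiedMolecule(
        molecule_id=genotype.molecule_id,
        category=cat,
        transition_intervals=tuple(transitions),
        converted_marker_ids=converted,
    )


def _converted_ids(
    informative: list[tuple[int, Call]], outer: Call, marker_map: MarkerMap
) -> tuple[str, ...]:
    return tuple(
        marker_map.markers[i].id for i, c in informative if c is not outer
    )


def exchange_interval(
    classified: ClassifiedMolecule, marker_map: MarkerMap
) -> tuple[int, int]:
    """Open bp interval containing a CO exchange point.

    Returns ``(position of last marker of the first haplotype, position of
    first marker of the second haplotype)``.  Use the midpoint when a point
    estimate of the breakpoint is needed.
    """
    if not classified.category.is_co:
        raise ValueError(
            f"exchange_interval requires a CO molecule, got {classified.category.value}"
        )
    left_id, right_id = classified.transition_intervals[0]
    left = marker_map.markers[marker_map.index_of(left_id)].position
    right = marker_map.markers[marker_map.index_of(right_id)].position
    return (left, right)


def interval_midpoint(interval: tuple[int, int]) -> float:
    """Midpoint breakpoint convention for an open exchange interval."""
    return (interval[0] + interval[1]) / 2.0
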