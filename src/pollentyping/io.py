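"""Readers and writers for the package's tabular interchange formats.

All files are TSV with named headers; readers validate header names (no
silent positional parsing) and reject malformed rows naming the offending
line.  Internal coordinates are 1-based inclusive bp; BED exports are
0-based half-open.  Rates are always serialized as proportions, never
percentages.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .dilution import DilutionEntry, DilutionSeries, PrimerKind
from .haplotypes import Call, Marker, MarkerMap, MoleculeGenotype
from .hotspot import BreakpointObservation, IntervalRateProfile, Orientation
from .nco import NCOEvent

__all__ = [
    "read_marker_map",
    "write_marker_map",
    "read_plate_table",
    "write_plate_table",
    "read_molecule_table",
    "write_molecule_table",
    "read_breakpoints",
    "write_breakpoints",
    "read_nco_events",
    "write_nco_events",
    "write_profile",
    "export_bed",
    "to_bed_interval",
    "from_bed_interval",
]

MARKER_COLUMNS = ["id", "position", "allele_P1", "allele_P2", "indel_size"]
PLATE_COLUMNS = ["primer_kind", "dilution", "wells", "negatives"]
BREAKPOINT_COLUMNS = ["molecule_id", "orientation", "left", "right"]
NCO_COLUMNS = ["molecule_id", "orientation", "converted_marker_ids", "chimeric"]


class TableFormatError(ValueError):
    """Malformed interchange file; the message names the line/column."""


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_marker_map(path: str | Path, region: str | None = None) -> MarkerMap:
    """Read a marker map TSV (id, position, allele_P1, allele_P2, indel_size)."""
    df = _read_tsv(path, MARKER_COLUMNS)
    markers = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            markers.append(
                Marker(
                    id=str(row["id"]),
                    position=int(row["position"]),
                    allele_p1=str(row["allele_P1"]),
                    allele_p2=str(row["allele_P2"]),
                    indel_size=int(row["indel_size"]),
                )
            )
        except (ValueError, TypeError) as e:
            raise TableFormatError(f"{path}: line {line}: {e}") from e
    positions = [m.position for m in markers]
    for i, (a, b) in enumerate(zip(positions, positions[1:])):
        if b <= a:
            raise TableFormatError(
                f"{path}: line {i + 3}: positions not strictly increasing "
                f"({b} after {a})"
            )
    return MarkerMap(region=region or Path(path).stem, markers=markers)


def write_marker_map(marker_map: MarkerMap, path: str | Path) -> None:
    rows = [
        {
            "id": m.id,
            "position": m.position,
            "allele_P1": m.allele_p1,
            "allele_P2": m.allele_p2,
            "indel_size": m.indel_size,
        }
        for m in marker_map.markers
    ]
    pd.DataFrame(rows, columns=MARKER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_plate_table(path: str | Path) -> dict[PrimerKind, DilutionSeries]:
    """Read dilution plates (primer_kind, dilution, wells, negatives) into
    one series per primer kind."""
    df = _read_tsv(path, PLATE_COLUMNS)
    entries: dict[PrimerKind, list[DilutionEntry]] = {}
    for i, row in df.iterrows():
        line = i + 2
        try:
            kind = PrimerKind(row["primer_kind"])
            entry = DilutionEntry(
                dilution=float(row["dilution"]),
                wells=int(row["wells"]),
                negatives=int(row["negatives"]),
            )
        except ValueError as e:
            raise TableFormatError(f"{path}: line {line}: {e}") from e
        entries.setdefault(kind, []).append(entry)
    return {k: DilutionSeries(k, v) for k, v in entries.items()}


def write_plate_table(
    series: Iterable[DilutionSeries], path: str | Path
) -> None:
    rows = [
        {
            "primer_kind": s.primer_kind.value,
            "dilution": e.dilution,
            "wells": e.wells,
            "negatives": e.negatives,
        }
        for s in series
        for e in s.entries
    ]
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_molecule_table(path: str | Path, marker_map: MarkerMap) -> list[MoleculeGenotype]:
    """Read a molecule genotype table: molecule_id plus one P1/P2/NA column
    per marker, in map order."""
    df = _read_tsv(path, ["molecule_id", *marker_map.ids])
    out = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            calls = [Call(str(row[mid])) for mid in marker_map.ids]
            out.append(MoleculeGenotype(str(row["molecule_id"]), calls))
        except ValueError as e:
            raise TableFormatError(f"{path}: line {line}: {e}") from e
    return out


def write_molecule_table(
    genotypes: Iterable[MoleculeGenotype], marker_map: MarkerMap, path: str | Path
) -> None:
    rows = []
    for g in genotypes:
        row = {"molecule_id": g.molecule_id}
        row.update({mid: c.value for mid, c in zip(marker_map.ids, g.calls)})
        rows.append(row)
    pd.DataFrame(rows, columns=["molecule_id", *marker_map.ids]).to_csv(
        path, sep="\t", index=False
    )


def read_breakpoints(path: str | Path) -> list[BreakpointObservation]:
    df = _read_tsv(path, BREAKPOINT_COLUMNS)
    out = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            out.append(
                BreakpointObservation(
                    orientation=Orientation(row["orientation"]),
                    left=int(row["left"]),
                    right=int(row["right"]),
                    molecule_id=str(row["molecule_id"]),
                )
            )
        except ValueError as e:
            raise TableFormatError(f"{path}: line {line}: {e}") from e
    return out


def write_breakpoints(
    breakpoints: Iterable[BreakpointObservation], path: str | Path
) -> None:
    rows = [
        {
            "molecule_id": bp.molecule_id,
            "orientation": bp.orientation.value,
            "left": bp.left,
            "right": bp.right,
        }
        for bp in breakpoints
    ]
    pd.DataFrame(rows, columns=BREAKPOINT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_nco_events(path: str | Path) -> list[NCOEvent]:
    df = _read_tsv(path, NCO_COLUMNS)
    out = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            out.append(
                NCOEvent(
                    molecule_id=str(row["molecule_id"]),
                    orientation=str(row["orientation"]),
                    converted_marker_ids=tuple(
                        str(row["converted_marker_ids"]).split(",")
                    ),
                    chimeric=str(row["chimeric"]).lower() in ("true", "1", "yes"),
                )
            )
        except ValueError as e:
            raise TableFormatError(f"{path}: line {line}: {e}") from e
    return out


def write_nco_events(events: Iterable[NCOEvent], path: str | Path) -> None:
    rows = [
        {
            "molecule_id": e.molecule_id,
            "orientation": e.orientation,
            "converted_marker_ids": ",".join(e.converted_marker_ids),
            "chimeric": e.chimeric,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=NCO_COLUMNS).to_csv(path, sep="\t", index=False)


def write_profile(profile: IntervalRateProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "interval_start": profile.starts.astype(int),
            "interval_end": profile.ends.astype(int),
            "count": profile.counts.astype(int),
            "cM_per_Mb": profile.rates_cM_Mb,
        }
    ).to_csv(path, sep="\t", index=False)


def to_bed_interval(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def from_bed_interval(start_0based: int, end_0based: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start_0based + 1, end_0based


def export_bed(
    intervals: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write (chrom, start_1based, end_1based, name) records as BED."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for chrom, start, end, name in intervals:
            b_start, b_end = to_bed_interval(start, end)
            writer.writerow([chrom, b_start, b_end, name])
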