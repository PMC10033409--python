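"""Receptor topology: ICL3 extraction and the mutation meta-analysis coordinate scheme.

The third intracellular loop (ICL3) of a class A GPCR connects transmembrane
helices 5 and 6. Because ICL3 length varies enormously between receptors
(roughly 10-240 residues), mutation effects reported at absolute residue
numbers are not comparable across receptors. This module implements:

* extraction of the ICL3 segment from an annotated receptor record (either an
  explicit ICL3 interval or the gap between the TM5 and TM6 annotations);
* a symmetric N/C numbering scheme in which the N-terminal half of the loop is
  counted N1..Nn from TM5 and the C-terminal half Cn..C1 back from TM6;
* linear rescaling of loop positions onto a common normalization length
  (default 22, the shortest ICL3 in the meta-analysis corpus, the length of
  the beta2AR loop 236-257);
* per-position aggregation of mutation effect sizes (delta = mutant - wild
  type on the pKd / pEC50 / Emax scale of each record).

All residue intervals are 1-based and inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReceptorRecord",
    "ICL3Segment",
    "MutationRecord",
    "MutationKind",
    "EffectMetric",
    "LoopCoordinate",
    "extract_icl3",
    "map_to_nc_coordinate",
    "nc_coordinate_to_position",
    "rescale_position",
    "aggregate_mutation_effects",
    "read_receptor_panel",
]

NORMALIZATION_LENGTH = 22


class AnnotationError(ValueError):
    """Raised when a record lacks the annotations needed for an operation."""


class MutationKind(str, Enum):
    substitution = "substitution"
    deletion = "deletion"
    chimera = "chimera"


class EffectMetric(str, Enum):
    pKd_agonist = "pKd_agonist"
    pEC50 = "pEC50"
    Emax = "Emax"


@dataclass(frozen=True)
class ICL3Segment:
    """An ICL3 residue interval (1-based, inclusive) with its sequence.

    The empty loop (adjacent TM5/TM6) is represented with the convention
    ``start == end + 1`` and ``length == 0``.
    """

    receptor_id: str
    start: int
    end: int
    subsequence: str

    def __post_init__(self) -> None:
        if self.length != len(self.subsequence):
            raise ValueError(
                f"interval width {self.length} != sequence length {len(self.subsequence)}"
            )

    @property
    def length(self) -> int:
        return max(self.end - self.start + 1, 0)


@dataclass
class ReceptorRecord:
    """A receptor sequence with structural-segment annotations.

    ``segments`` maps element labels (TM5, TM6, ICL3, ...) to 1-based
    inclusive residue intervals. ``coupling`` is the set of transducer
    families ({"Gs", "Gi", "Gq", "G12"}) the receptor couples to.
    """

    receptor_id: str
    sequence: str
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)
    coupling: frozenset[str] = frozenset()
    receptor_class: str = "A"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for label, (start, end) in self.segments.items():
            if not (1 <= start and end <= n and start <= end):
                raise ValueError(
                    f"{self.receptor_id}: segment {label} ({start}, {end}) "
                    f"outside sequence bounds [1, {n}]"
                )


@dataclass(frozen=True)
class MutationRecord:
    """One literature mutation report with a wild-type reference point.

    ``positions`` are ICL3-relative 1-based positions of the mutated
    residues; a multi-residue mutant (e.g. QDG->AAA) lists all of them and
    contributes its single effect size to each.
    """

    receptor_id: str
    positions: tuple[int, ...]
    mutation_kind: MutationKind
    metric: EffectMetric
    wt_value: float
    mut_value: float

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("positions must be non-empty")

    @property
    def delta(self) -> float:
        return self.mut_value - self.wt_value


@dataclass(frozen=True)
class LoopCoordinate:
    """A loop position in N/C numbering: N1..Nn counted from the TM5 side,
    Cn..C1 counted back from the TM6 side."""

    side: str  # "N" or "C"
    rank: int

    def __post_init__(self) -> None:
        if self.side not in ("N", "C"):
            raise ValueError(f"side must be 'N' or 'C', got {self.side!r}")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")

    def __str__(self) -> str:
        return f"{self.side}{self.rank}"


def extract_icl3(receptor: ReceptorRecord) -> ICL3Segment:
    """Extract the ICL3 segment of a receptor.

    Preference order: an explicit ``ICL3`` annotation, else the gap between
    the TM5 and TM6 intervals (last TM5 residue + 1 .. first TM6 residue - 1).
    Adjacent helices yield the empty segment (length 0).
    """
    segs = receptor.segments
    if "ICL3" in segs:
        start, end = segs["ICL3"]
    elif "TM5" in segs and "TM6" in segs:
        start = segs["TM5"][1] + 1
        end = segs["TM6"][0] - 1
        if end < start - 1:
            raise AnnotationError(
                f"{receptor.receptor_id}: TM5/TM6 annotations overlap "
                f"(TM5 end {segs['TM5'][1]}, TM6 start {segs['TM6'][0]})"
            )
    else:
        raise AnnotationError(
            f"{receptor.receptor_id}: needs an ICL3 annotation or both TM5 and TM6"
        )
    if end >= start and not (1 <= start and end <= len(receptor.sequence)):
        raise AnnotationError(
            f"{receptor.receptor_id}: ICL3 interval ({start}, {end}) out of bounds"
        )
    sub = receptor.sequence[start - 1 : end] if end >= start else ""
    return ICL3Segment(receptor.receptor_id, start, end, sub)


def map_to_nc_coordinate(position: int, icl3_length: int) -> LoopCoordinate:
    """Map an ICL3-relative position to N/C numbering.

    Positions in the first half map to (N, p); positions in the second half
    map to (C, L - p + 1). For odd L the middle position ceil(L/2) is
    assigned to the N side.
    """
    if icl3_length < 1:
        raise ValueError("icl3_length must be >= 1")
    if not 1 <= position <= icl3_length:
        raise ValueError(f"position {position} outside [1, {icl3_length}]")
    n_half = math.ceil(icl3_length / 2)
    if position <= n_half:
        return LoopCoordinate("N", position)
    return LoopCoordinate("C", icl3_length - position + 1)


def nc_coordinate_to_position(coord: LoopCoordinate, icl3_length: int) -> int:
    """Inverse of :func:`map_to_nc_coordinate`."""
    n_half = math.ceil(icl3_length / 2)
    if coord.side == "N":
        if coord.rank > n_half:
            raise ValueError(f"N{coord.rank} does not exist for length {icl3_length}")
        return coord.rank
    if coord.rank > icl3_length - n_half:
        raise ValueError(f"C{coord.rank} does not exist for length {icl3_length}")
    return icl3_length - coord.rank + 1


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def rescale_position(
    position: int, source_length: int, target_length: int = NORMALIZATION_LENGTH
) -> int:
    """Linearly rescale a 1-based loop position onto a shorter target frame.

    Bin centres are mapped proportionally (p -> (p - 0.5) * target/source + 0.5),
    rounded half-up and clamped to [1, target_length], so the rescale map is
    monotone and endpoints map to endpoints.
    """
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    if target_length > source_length:
        raise ValueError(
            f"target_length {target_length} exceeds source_length {source_length}"
        )
    if not 1 <= position <= source_length:
        raise ValueError(f"position {position} outside [1, {source_length}]")
    scaled = (position - 0.5) * target_length / source_length + 0.5
    return min(max(_round_half_up(scaled), 1), target_length)


def aggregate_mutation_effects(
    records: Iterable[MutationRecord],
    host_lengths: Mapping[str, int],
    target_length: int = NORMALIZATION_LENGTH,
    include_chimeras: bool = False,
) -> pd.DataFrame:
    """Aggregate mutation effect sizes per normalized loop position and metric.

    Every mutated position of a record receives that record's delta
    (mut - wt); positions are rescaled onto ``target_length``. Chimera
    records are excluded unless ``include_chimeras`` is set. Returns a tidy
    frame with one row per (normalized position, metric) carrying the list of
    deltas, their count and mean.
    """
    table: dict[tuple[int, str], list[float]] = {}
    for rec in records:
        if rec.mutation_kind is MutationKind.chimera and not include_chimeras:
            continue
        if rec.receptor_id not in host_lengths:
            raise KeyError(f"unknown host ICL3 length for {rec.receptor_id}")
        length = host_lengths[rec.receptor_id]
        for pos in rec.positions:
            if not 1 <= pos <= length:
                raise ValueError(
                    f"{rec.receptor_id}: position {pos} outside ICL3 of length {length}"
                )
            norm = rescale_position(pos, length, target_length)
            table.setdefault((norm, rec.metric.value), []).append(rec.delta)
    rows = [
        {
            "position": pos,
            "metric": metric,
            "deltas": deltas,
            "count": len(deltas),
            "mean_delta": sum(deltas) / len(deltas),
        }
        for (pos, metric), deltas in sorted(table.items())
    ]
    return pd.DataFrame(
        rows, columns=["position", "metric", "deltas", "count", "mean_delta"]
    )


def read_receptor_panel(fasta_path, annotation_path) -> list[ReceptorRecord]:
    """Read a receptor panel from FASTA sequences plus a TSV annotation table.

    The annotation table needs columns ``receptor_id``, ``element``,
    ``start``, ``end`` and optionally ``coupling`` (semicolon-separated
    families) and ``class``.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    annot = pd.read_csv(annotation_path, sep="\t")
    records = []
    for rid, grp in annot.groupby("receptor_id", sort=False):
        if rid not in seqs:
            raise KeyError(f"receptor {rid} missing from FASTA")
        segments = {
            row.element: (int(row.start), int(row.end)) for row in grp.itertuples()
        }
        coupling: frozenset[str] = frozenset()
        if "coupling" in grp.columns:
            raw = grp["coupling"].dropna()
            if len(raw):
                coupling = frozenset(
                    f for cell in raw for f in str(cell).split(";") if f
                )
        rclass = str(grp["class"].iloc[0]) if "class" in grp.columns else "A"
        records.append(
            ReceptorRecord(
                receptor_id=str(rid),
                sequence=seqs[rid],
                segments=segments,
                coupling=coupling,
                receptor_class=rclass,
            )
        )
    return records
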