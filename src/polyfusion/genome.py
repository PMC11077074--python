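"""Toy reference genomes, structural-variant haplotypes and coordinate liftover.

The synthetic locus emulated throughout the package is a two-gene region in
opposing orientations (a pseudogene/gene pair on one contig), on which a
structural variant — a deletion, tandem duplication, inversion, or an
inversion with an adjacent deletion — creates one or more novel DNA
adjacencies capable of producing a fusion transcript.

Coordinates are 0-based half-open everywhere in this module; 1-based
coordinates appear only in SAM/BED-style emissions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GeneModel",
    "ToyGenomeSpec",
    "Genome",
    "SVSpec",
    "Segment",
    "Junction",
    "Haplotype",
    "build_genome",
    "apply_sv",
    "revcomp",
    "reference_haplotype",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SV_TYPES = ("DEL", "DUP", "INV", "COMPLEX_INV_DEL")

#: flank length (bp) carried on each side of an emitted junction record
JUNCTION_FLANK = 70


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when a spec violates its structural invariants."""


@dataclass(frozen=True)
class GeneModel:
    """A gene on the toy contig: strand, exons and optional CDS intervals.

    Exons and CDS intervals are 0-based half-open ``(start, end)`` pairs,
    sorted and non-overlapping; every CDS interval must lie within an exon.
    """

    name: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def validate(self, contig_length: int) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.name}: strand must be + or -")
        prev_end = None
        for start, end in self.exons:
            if not (0 <= start < end <= contig_length):
                raise ValidationError(
                    f"gene {self.name}: exon [{start},{end}) outside contig "
                    f"of length {contig_length}"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"gene {self.name}: exons overlap or are unsorted at {start}"
                )
            prev_end = end
        for cstart, cend in self.cds:
            if not any(s <= cstart and cend <= e for s, e in self.exons):
                raise ValidationError(
                    f"gene {self.name}: CDS [{cstart},{cend}) not contained in an exon"
                )

    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class ToyGenomeSpec:
    contig_name: str
    length: int
    genes: tuple[GeneModel, ...]
    seed: int = 0

    def validate(self) -> None:
        if self.length <= 0:
            raise ValidationError("contig length must be positive")
        for gene in self.genes:
            gene.validate(self.length)


@dataclass
class Genome:
    """A built toy reference: one contig plus its gene annotation."""

    contig_name: str
    sequence: str
    genes: tuple[GeneModel, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)

    def write_fasta(self, path, line_width: int = 80) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.contig_name}\n")
            for i in range(0, len(self.sequence), line_width):
                fh.write(self.sequence[i : i + line_width] + "\n")

    def exon_bed_records(self) -> list[tuple]:
        """BED6 rows (contig, start, end, name, score, strand), one per exon."""
        rows = []
        for gene in self.genes:
            for i, (start, end) in enumerate(gene.exons):
                rows.append(
                    (self.contig_name, start, end, f"{gene.name}_exon{i + 1}", 0, gene.strand)
                )
        return rows

    def write_exon_bed(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.exon_bed_records():
                fh.write("\t".join(str(x) for x in row) + "\n")

    def gene_span(self, name: str) -> tuple[int, int]:
        for gene in self.genes:
            if gene.name == name:
                return gene.span()
        raise KeyError(name)


def build_genome(spec: ToyGenomeSpec) -> Genome:
    """Generate a random reference sequence for *spec* (deterministic in seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    idx = rng.integers(0, 4, size=spec.length)
    sequence = alphabet[idx].tobytes().decode("ascii")
    return Genome(spec.contig_name, sequence, tuple(spec.genes))


@dataclass(frozen=True)
class SVSpec:
    """A structural variant to plant on the toy reference.

    ``breakpoints`` holds the affected 0-based half-open intervals:
    one interval for DEL/DUP/INV; for COMPLEX_INV_DEL exactly two —
    the inversion interval followed by the immediately adjacent
    deletion interval.
    """

    sv_id: str
    sv_type: str
    breakpoints: tuple[tuple[int, int], ...]
    expected_fusion: tuple[str, str] | None = None

    def validate(self, contig_length: int) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValidationError(f"unknown sv_type {self.sv_type!r}")
        if self.sv_type == "COMPLEX_INV_DEL":
            if len(self.breakpoints) != 2:
                raise ValidationError(
                    "COMPLEX_INV_DEL requires exactly one inversion and one "
                    "adjacent deletion interval"
                )
            (a, b), (c, d) = self.breakpoints
            if b != c:
                raise ValidationError("deletion interval must be adjacent to the inversion")
        elif len(self.breakpoints) != 1:
            raise ValidationError(f"{self.sv_type} requires exactly one interval")
        prev = 0
        for start, end in self.breakpoints:
            if not (0 <= start < end <= contig_length):
                raise ValidationError(f"interval [{start},{end}) outside contig")
            if start < prev:
                raise ValidationError("intervals must be sorted and non-overlapping")
            prev = end


@dataclass(frozen=True)
class Segment:
    """A maximal colinear block of the haplotype→reference mapping.

    Haplotype positions ``[hap_start, hap_end)`` map to reference positions
    ``[ref_start, ref_start + (hap_end - hap_start))``.  ``strand`` is +1 for
    a colinear block and −1 for an inverted block, in which case haplotype
    position ``h`` maps to reference ``ref_start + (hap_end - 1 - h)``.
    """

    hap_start: int
    hap_end: int
    ref_start: int
    strand: int


@dataclass(frozen=True)
class Junction:
    """A novel adjacency on the alternate haplotype, with flanking sequence."""

    name: str
    hap_pos: int
    sequence: str


@dataclass
class Haplotype:
    """An allele sequence with its piecewise mapping back to the reference."""

    sequence: str
    segments: tuple[Segment, ...]
    junctions: tuple[Junction, ...] = ()
    sv_id: str = "ref"

    @property
    def length(self) -> int:
        return len(self.sequence)

    def lift_reads(
        self, starts: np.ndarray, ends: np.ndarray, strands: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map haplotype read intervals to reference space.

        Each read ``[start, end)`` with haplotype strand ±1 is assigned to the
        segment containing its midpoint; reads crossing a segment boundary are
        flagged split.  Returns ``(ref_left, ref_strand, split_flag)`` where
        ``ref_left`` is the leftmost reference coordinate of the read.
        """
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        strands = np.asarray(strands)
        hap_starts = np.array([s.hap_start for s in self.segments])
        hap_ends = np.array([s.hap_end for s in self.segments])
        ref_starts = np.array([s.ref_start for s in self.segments])
        seg_strand = np.array([s.strand for s in self.segments])

        mid = (starts + ends) // 2
        idx = np.searchsorted(hap_starts, mid, side="right") - 1
        idx = np.clip(idx, 0, len(self.segments) - 1)

        fwd = seg_strand[idx] == 1
        ref_left = np.where(
            fwd,
            ref_starts[idx] + (starts - hap_starts[idx]),
            ref_starts[idx] + (hap_ends[idx] - ends),
        )
        ref_strand = strands * seg_strand[idx]
        split = (starts < hap_starts[idx]) | (ends > hap_ends[idx])
        return ref_left, ref_strand, split

    def lift_positions(self, positions: np.ndarray) -> np.ndarray:
        """Point liftover haplotype→reference (vectorized)."""
        positions = np.asarray(positions)
        hap_starts = np.array([s.hap_start for s in self.segments])
        hap_ends = np.array([s.hap_end for s in self.segments])
        ref_starts = np.array([s.ref_start for s in self.segments])
        seg_strand = np.array([s.strand for s in self.segments])
        idx = np.searchsorted(hap_starts, positions, side="right") - 1
        idx = np.clip(idx, 0, len(self.segments) - 1)
        return np.where(
            seg_strand[idx] == 1,
            ref_starts[idx] + (positions - hap_starts[idx]),
            ref_starts[idx] + (hap_ends[idx] - 1 - positions),
        )


def reference_haplotype(reference: str) -> Haplotype:
    """The identity haplotype (genotype-0 allele)."""
    return Haplotype(reference, (Segment(0, len(reference), 0, 1),), (), "ref")


def _junction(name: str, seq: str, pos: int, flank: int = JUNCTION_FLANK) -> Junction:
    lo = max(0, pos - flank)
    hi = min(len(seq), pos + flank)
    return Junction(name, pos, seq[lo:hi])


def apply_sv(reference: str, sv: SVSpec) -> Haplotype:
    """Construct the alternate haplotype for *sv* and its junction records.

    DEL removes its interval; DUP inserts a tandem copy; INV reverse-
    complements in place; COMPLEX_INV_DEL inverts its first interval and
    removes the adjacent second.  One junction record (with ±70 bp flanks)
    is emitted per novel adjacency.
    """
    sv.validate(len(reference))
    n = len(reference)
    if sv.sv_type == "DEL":
        (a, b), = sv.breakpoints
        seq = reference[:a] + reference[b:]
        segments = (Segment(0, a, 0, 1), Segment(a, n - (b - a), b, 1))
        junctions = (_junction(f"{sv.sv_id}_bp", seq, a),)
    elif sv.sv_type == "DUP":
        (a, b), = sv.breakpoints
        seq = reference[:b] + reference[a:b] + reference[b:]
        d = b - a
        segments = (
            Segment(0, b, 0, 1),
            Segment(b, b + d, a, 1),
            Segment(b + d, n + d, b, 1),
        )
        junctions = (_junction(f"{sv.sv_id}_bp", seq, b),)
    elif sv.sv_type == "INV":
        (a, b), = sv.breakpoints
        seq = reference[:a] + revcomp(reference[a:b]) + reference[b:]
        segments = (Segment(0, a, 0, 1), Segment(a, b, a, -1), Segment(b, n, b, 1))
        junctions = (
            _junction(f"{sv.sv_id}_bp1", seq, a),
            _junction(f"{sv.sv_id}_bp2", seq, b),
        )
    elif sv.sv_type == "COMPLEX_INV_DEL":
        (a, b), (_, c) = sv.breakpoints
        seq = reference[:a] + revcomp(reference[a:b]) + reference[c:]
        segments = (
            Segment(0, a, 0, 1),
            Segment(a, b, a, -1),
            Segment(b, len(seq), c, 1),
        )
        junctions = (
            _junction(f"{sv.sv_id}_bp1", seq, a),
            _junction(f"{sv.sv_id}_bp2", seq, b),
        )
    else:  # pragma: no cover - guarded by validate
        raise ValidationError(sv.sv_type)
    return Haplotype(seq, segments, junctions, sv.sv_id)
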