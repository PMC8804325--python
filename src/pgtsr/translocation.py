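"""Reciprocal translocations and derivative chromosomes.

A reciprocal translocation exchanges the distal fragments of two
non-homologous chromosomes, producing two derivative chromosomes der(A) and
der(B), each monocentric, joined at a breakpoint junction that may carry a
short non-templated insertion (non-homologous end joining typically leaves
fewer than 40 inserted bases).

Conventions
-----------
* Coordinates are 1-based inclusive.
* The breakpoint position bounds the *retained-proximal* side: for a q-arm
  breakpoint, bases ``[1..pos]`` stay with the centromere and ``[pos+1..len]``
  are exchanged; for a p-arm breakpoint the distal ``[1..pos]`` fragment is
  exchanged and ``[pos+1..len]`` stays.
* Derivative segments are listed pter -> qter; a segment on strand ``-`` is
  read descending in reference coordinates (mixed p/q exchanges attach one
  fragment tail-first, so one segment of each derivative is inverted in
  reference orientation while the chromosome itself remains monocentric).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import GenomeBuild

_VALID_BASES = set("ACGTacgt")
MAX_INSERTION = 40  # junction micro-insertions are < 40 bases


@dataclass(frozen=True)
class Segment:
    """A reference interval on a derivative, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranslocationSpec:
    """A reciprocal translocation between ``chromA`` and ``chromB``.

    ``posA``/``posB`` are the breakpoint positions (see module conventions);
    ``insertionA``/``insertionB`` are the junction insertions carried by
    der(A) and der(B) respectively (0-39 bases each); ``armA``/``armB`` name
    the exchanged arm of each chromosome.
    """

    chromA: str
    posA: int
    chromB: str
    posB: int
    armA: str = "q"
    armB: str = "q"
    insertionA: str = ""
    insertionB: str = ""

    def __post_init__(self):
        if self.chromA == self.chromB:
            raise ValueError("reciprocal translocation requires two distinct chromosomes")
        for arm in (self.armA, self.armB):
            if arm not in ("p", "q"):
                raise ValueError(f"arm must be 'p' or 'q', got {arm!r}")
        for ins in (self.insertionA, self.insertionB):
            if len(ins) >= MAX_INSERTION:
                raise ValueError(f"junction insertion must be < {MAX_INSERTION} bases")
            if not set(ins) <= _VALID_BASES:
                raise ValueError(f"invalid bases in insertion {ins!r}")

    def validate(self, genome: GenomeBuild) -> None:
        for chrom, pos in ((self.chromA, self.posA), (self.chromB, self.posB)):
            if chrom not in genome:
                raise ValueError(f"unknown chromosome {chrom}")
            if not 1 <= pos <= genome.length(chrom):
                raise ValueError(f"breakpoint {chrom}:{pos} outside chromosome")


@dataclass
class DerivativeChromosome:
    """An ordered list of reference segments joined by one junction insertion.

    ``junction_offset`` is the derivative coordinate (1-based) of the last
    base of the first segment; the insertion (possibly empty) occupies
    ``[junction_offset+1 .. junction_offset+len(insertion)]``.
    """

    name: str
    segments: list[Segment]
    insertion: str = ""

    @property
    def junction_offset(self) -> int:
        return len(self.segments[0])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.segments) + len(self.insertion)

    def __len__(self) -> int:
        return self.total_length

    def _pieces(self) -> list[tuple[int, int, Segment | None]]:
        """(derivative start, derivative end, segment-or-None) per piece;
        ``None`` marks the insertion."""
        out: list[tuple[int, int, Segment | None]] = []
        offset = 0
        for i, seg in enumerate(self.segments):
            out.append((offset + 1, offset + len(seg), seg))
            offset += len(seg)
            if i == 0 and self.insertion:
                out.append((offset + 1, offset + len(self.insertion), None))
                offset += len(self.insertion)
        return out

    def ref_coord(self, offset: int) -> tuple[str | None, int, str]:
        """Map a derivative offset (1-based) to ``(chrom, position, strand)``.

        Offsets falling inside the junction insertion map to
        ``(None, index_within_insertion, '+')``.
        """
        if not 1 <= offset <= self.total_length:
            raise ValueError(f"offset {offset} outside derivative (len {self.total_length})")
        for lo, hi, seg in self._pieces():
            if lo <= offset <= hi:
                i = offset - lo + 1  # 1-based within piece
                if seg is None:
                    return None, i, "+"
                if seg.strand == "+":
                    return seg.chrom, seg.start + i - 1, "+"
                return seg.chrom, seg.end - i + 1, "-"
        raise AssertionError("unreachable")

    def map_interval(self, d_start: int, d_end: int) -> list[tuple[Segment, int, int]]:
        """Intersect a derivative interval with the pieces.

        Returns ``(reference segment clipped to the overlap, derivative start,
        derivative end)`` per overlapped reference piece, in derivative order;
        insertion overlap yields a ``Segment`` with ``chrom=''`` sentinel? --
        insertions are skipped (they have no reference coordinates).
        """
        if d_start > d_end:
            raise ValueError("empty interval")
        out = []
        for lo, hi, seg in self._pieces():
            a, b = max(lo, d_start), min(hi, d_end)
            if a > b or seg is None:
                continue
            if seg.strand == "+":
                clipped = Segment(seg.chrom, seg.start + (a - lo), seg.start + (b - lo), "+")
            else:
                clipped = Segment(seg.chrom, seg.end - (b - lo), seg.end - (a - lo), "-")
            out.append((clipped, a, b))
        return out

    def sequence(self, genome: GenomeBuild, d_start: int = 1, d_end: int | None = None) -> str:
        """Synthetic sequence of the derivative over [d_start, d_end]."""
        from Bio.Seq import reverse_complement

        if d_end is None:
            d_end = self.total_length
        parts = []
        for lo, hi, seg in self._pieces():
            a, b = max(lo, d_start), min(hi, d_end)
            if a > b:
                continue
            if seg is None:
                parts.append(self.insertion[a - lo : b - lo + 1])
            elif seg.strand == "+":
                parts.append(genome.sequence(seg.chrom, seg.start + (a - lo), seg.start + (b - lo)))
            else:
                raw = genome.sequence(seg.chrom, seg.end - (b - lo), seg.end - (a - lo))
                parts.append(reverse_complement(raw))
        return "".join(parts)


def make_derivatives(
    genome: GenomeBuild, spec: TranslocationSpec
) -> tuple[DerivativeChromosome, DerivativeChromosome]:
    """Build der(A) and der(B) for a reciprocal exchange.

    der(A) is the derivative carrying chromosome A's centromere, der(B)
    carries B's. For a q/q exchange::

        der(A) = A[1..posA] ++ insertionA ++ B[posB+1..lenB]
        der(B) = B[1..posB] ++ insertionB ++ A[posA+1..lenA]

    A p-arm breakpoint exchanges the distal ``[1..pos]`` fragment instead,
    and a mixed p/q exchange attaches the incoming fragment break-end first,
    i.e. inverted in reference orientation.
    """
    spec.validate(genome)
    a, b = spec.chromA, spec.chromB
    pa, pb = spec.posA, spec.posB
    la, lb = genome.length(a), genome.length(b)

    # centric (retained) fragment of each chromosome
    centric_a = Segment(a, 1, pa, "+") if spec.armA == "q" else Segment(a, pa + 1, la, "+")
    centric_b = Segment(b, 1, pb, "+") if spec.armB == "q" else Segment(b, pb + 1, lb, "+")
    # distal (exchanged) fragment
    distal_a = Segment(a, pa + 1, la, "+") if spec.armA == "q" else Segment(a, 1, pa, "+")
    distal_b = Segment(b, pb + 1, lb, "+") if spec.armB == "q" else Segment(b, 1, pb, "+")

    def join(centric: Segment, incoming: Segment, centric_arm: str, incoming_arm: str,
             name: str, insertion: str) -> DerivativeChromosome:
        # A fragment broken on the same arm class as the acceptor keeps its
        # reference orientation; opposite arm classes attach break-end first.
        flip = centric_arm != incoming_arm
        if flip:
            incoming = Segment(incoming.chrom, incoming.start, incoming.end, "-")
        if centric_arm == "q":
            # junction at the centric fragment's distal (right) end
            segs = [centric, incoming]
        else:
            segs = [incoming, centric]
        return DerivativeChromosome(name, segs, insertion)

    num_a = a.removeprefix("chr")
    num_b = b.removeprefix("chr")
    der_a = join(centric_a, distal_b, spec.armA, spec.armB, f"der({num_a})", spec.insertionA)
    der_b = join(centric_b, distal_a, spec.armB, spec.armA, f"der({num_b})", spec.insertionB)
    return der_a, der_b
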