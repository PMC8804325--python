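"""Translocation breakpoint calling from chimeric split-read alignments.

Each multi-segment read contributes one junction signal per adjacent pair of
segments on different chromosomes: the two breakend coordinates plus a
breakend orientation per side ('R': the retained sequence extends to lower
coordinates, the junction is at the segment's right edge; 'L': the reverse).
Signals sharing (chromosome pair, orientation pair) whose positions agree on
both sides within a merge window cluster into one candidate; the cluster
position is the lower median of member positions. Candidates with at least
``min_support`` distinct spanning reads pass; the rest are flagged
low-support. A reciprocal translocation produces two distinct junction
classes — one per derivative chromosome — which never merge because their
orientation pairs differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .genome import GenomeBuild
from .observe import SplitRead

DEFAULT_MIN_SUPPORT = 2  # a junction needs >= 2 spanning reads to pass
DEFAULT_MERGE_WINDOW = 1000  # bp


@dataclass(frozen=True)
class JunctionSignal:
    """One breakend pair from one read, canonically ordered by (chrom, pos)."""

    chromA: str
    posA: int
    orientA: str
    chromB: str
    posB: int
    orientB: str
    read_id: str

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.chromA, self.orientA, self.chromB, self.orientB)


@dataclass
class Cluster:
    chromA: str
    orientA: str
    chromB: str
    orientB: str
    positionsA: list[int] = field(default_factory=list)
    positionsB: list[int] = field(default_factory=list)
    read_ids: list[str] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(set(self.read_ids))

    @staticmethod
    def _lower_median(xs: list[int]) -> int:
        s = sorted(xs)
        return s[(len(s) - 1) // 2]

    @property
    def posA(self) -> int:
        return self._lower_median(self.positionsA)

    @property
    def posB(self) -> int:
        return self._lower_median(self.positionsB)


@dataclass
class TranslocationCall:
    """A clustered, filtered translocation breakpoint call."""

    chromA: str
    posA: int
    orientA: str
    chromB: str
    posB: int
    orientB: str
    support: int
    read_ids: list[str]
    filter: str  # "pass" | "low_support"

    @property
    def passed(self) -> bool:
        return self.filter == "pass"


def junction_signals(reads: list[SplitRead]) -> list[JunctionSignal]:
    """Extract inter-chromosomal junction signals; single-segment reads and
    same-chromosome adjacencies contribute nothing."""
    out = []
    for read in reads:
        segs = sorted(read.segments, key=lambda s: s.read_start)
        for left, right in zip(segs, segs[1:]):
            if left.chrom == right.chrom:
                continue
            # breakend of the left segment is at its read_end side
            if left.strand == "+":
                pos1, or1 = left.ref_end, "R"
            else:
                pos1, or1 = left.ref_start, "L"
            if right.strand == "+":
                pos2, or2 = right.ref_start, "L"
            else:
                pos2, or2 = right.ref_end, "R"
            side1 = (left.chrom, pos1, or1)
            side2 = (right.chrom, pos2, or2)
            if (side2[0], side2[1]) < (side1[0], side1[1]):
                side1, side2 = side2, side1
            out.append(JunctionSignal(*side1, *side2, read.read_id))
    return out


def cluster_chimeric_reads(
    reads: list[SplitRead], merge_window: int = DEFAULT_MERGE_WINDOW
) -> list[Cluster]:
    """Single-linkage clustering of junction signals within ``merge_window``
    on both sides, separately per (chromosome pair, orientation pair)."""
    if merge_window <= 0:
        raise ValueError("merge_window must be positive")
    by_key: dict[tuple, list[JunctionSignal]] = {}
    for sig in junction_signals(reads):
        by_key.setdefault(sig.key, []).append(sig)
    clusters: list[Cluster] = []
    for key, sigs in sorted(by_key.items()):
        sigs.sort(key=lambda s: (s.posA, s.posB))
        current: Cluster | None = None
        for sig in sigs:
            if (
                current is not None
                and abs(sig.posA - current.positionsA[-1]) <= merge_window
                and abs(sig.posB - current.positionsB[-1]) <= merge_window
            ):
                pass
            else:
                current = Cluster(sig.chromA, sig.orientA, sig.chromB, sig.orientB)
                clusters.append(current)
            current.positionsA.append(sig.posA)
            current.positionsB.append(sig.posB)
            current.read_ids.append(sig.read_id)
    return clusters


def call_translocations(
    clusters: list[Cluster], min_support: int = DEFAULT_MIN_SUPPORT
) -> list[TranslocationCall]:
    """Apply the support filter (pass iff >= ``min_support`` distinct reads)
    and sort calls by (chromA, posA)."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    calls = [
        TranslocationCall(
            c.chromA, c.posA, c.orientA, c.chromB, c.posB, c.orientB,
            c.support, sorted(set(c.read_ids)),
            "pass" if c.support >= min_support else "low_support",
        )
        for c in clusters
    ]
    calls.sort(key=lambda c: (c.chromA, c.posA, c.chromB, c.posB))
    return calls


# ---------------------------------------------------------------------------
# Gene annotation


@dataclass(frozen=True)
class GeneInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    name: str


class GeneModel:
    """Gene intervals indexed per chromosome for breakpoint annotation."""

    def __init__(self, intervals: list[GeneInterval]):
        self._by_chrom: dict[str, list[GeneInterval]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in self._by_chrom.values():
            ivs.sort(key=lambda g: (g.start, g.end))

    def annotate(self, chrom: str, pos: int) -> str:
        """``disrupted:<gene>`` if pos lies inside a gene, else
        ``intergenic:<left>|<right>`` with ``none`` for a missing neighbor."""
        if chrom not in self._by_chrom:
            raise KeyError(f"no gene model for chromosome {chrom}")
        left, right = None, None
        for g in self._by_chrom[chrom]:
            if g.start <= pos <= g.end:
                return f"disrupted:{g.name}"
            if g.end < pos and (left is None or g.end > left.end):
                left = g
            if g.start > pos and (right is None or g.start < right.start):
                right = g
        return f"intergenic:{left.name if left else 'none'}|{right.name if right else 'none'}"


def annotate_breakpoint(call: TranslocationCall, genes: GeneModel) -> tuple[str, str]:
    """Per-side gene annotation of a translocation call."""
    return genes.annotate(call.chromA, call.posA), genes.annotate(call.chromB, call.posB)


# ---------------------------------------------------------------------------
# Segment metrics


@dataclass(frozen=True)
class SegmentMetrics:
    """Translocated-segment size summary for one breakpoint side."""

    length_bp: int
    length_mb: float  # rounded half-up, 2 decimals
    percent: float  # of source chromosome, rounded half-up, 2 decimals
    arm: str


def _round2(x: float | Decimal) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def segment_metrics(
    chrom: str, pos: int, genome: GenomeBuild, arm: str | None = None
) -> SegmentMetrics:
    """Size of the translocated (distal) segment for a breakpoint.

    A q-arm breakpoint exchanges ``length - pos`` distal bases; a p-arm
    breakpoint exchanges the distal ``pos`` bases. The arm is resolved from
    the genome's cytoband table unless given explicitly.
    """
    chrom_len = genome.length(chrom)
    if not 1 <= pos <= chrom_len:
        raise ValueError(f"position {pos} outside {chrom} (len {chrom_len})")
    if arm is None:
        arm = genome.arm_of(chrom, pos)
    if arm not in ("p", "q"):
        raise ValueError(f"arm must be 'p' or 'q', got {arm!r}")
    length = chrom_len - pos if arm == "q" else pos
    return SegmentMetrics(
        length_bp=length,
        length_mb=_round2(Decimal(length) / Decimal(10**6)),
        percent=_round2(Decimal(100 * length) / Decimal(chrom_len)),
        arm=arm,
    )


# ---------------------------------------------------------------------------
# Public SV-database overlap annotation


@dataclass(frozen=True)
class SVDatabaseRecord:
    """One record of a population SV database (BED-like)."""

    svtype: str  # DEL | INS | DUP | INV | TRA
    chrom: str
    start: int
    end: int
    source: str = "db"
    chrom2: str | None = None  # TRA partner breakend
    pos2: int | None = None


def reciprocal_overlap(s1: int, e1: int, s2: int, e2: int) -> float:
    """Reciprocal overlap of two 1-based inclusive intervals: the shared
    length divided by the longer requirement (min of the two per-interval
    fractions). Symmetric by construction."""
    inter = min(e1, e2) - max(s1, s2) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (e1 - s1 + 1), inter / (e2 - s2 + 1))


def db_overlap(
    svtype: str,
    chrom: str,
    start: int,
    end: int,
    database: list[SVDatabaseRecord],
    overlap_frac: float = 0.5,
    ins_dist: int = 1000,
    chrom2: str | None = None,
    pos2: int | None = None,
) -> list[str]:
    """Database source labels matching a query SV.

    Interval types (DEL/DUP/INV) match on reciprocal overlap >=
    ``overlap_frac``; INS matches when the positions differ by <=
    ``ins_dist``; TRA matches when both breakends are within ``ins_dist``
    of a database TRA's breakends.
    """
    if not 0 < overlap_frac <= 1:
        raise ValueError("overlap_frac must be in (0, 1]")
    if ins_dist < 0:
        raise ValueError("ins_dist must be >= 0")
    hits = []
    for rec in database:
        if rec.svtype != svtype:
            continue
        if svtype == "INS":
            if rec.chrom == chrom and abs(rec.start - start) <= ins_dist:
                hits.append(rec.source)
        elif svtype == "TRA":
            if chrom2 is None or pos2 is None or rec.chrom2 is None or rec.pos2 is None:
                continue
            ends_q = {(chrom, start), (chrom2, pos2)}
            ok = all(
                any(c == rc and abs(p - rp) <= ins_dist for rc, rp in
                    [(rec.chrom, rec.start), (rec.chrom2, rec.pos2)])
                for c, p in ends_q
            )
            if ok:
                hits.append(rec.source)
        else:
            if rec.chrom == chrom and reciprocal_overlap(start, end, rec.start, rec.end) >= overlap_frac:
                hits.append(rec.source)
    return hits
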