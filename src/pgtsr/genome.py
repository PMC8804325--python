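"""Genome builds: chromosome lengths, cytobands, and deterministic synthetic sequence.

A :class:`GenomeBuild` is the coordinate frame every other module works in.
Coordinates are 1-based inclusive internally; cytoband TSV input/output uses the
UCSC 0-based half-open dialect. Synthetic sequence is generated lazily in fixed
blocks keyed by ``(seed, chromosome, block)``, so any slice of any chromosome is
reproducible without materialising the whole chromosome.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BLOCK = 1 << 16


@dataclass(frozen=True)
class Cytoband:
    """One Giemsa band, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    name: str  # e.g. "q44"

    @property
    def arm(self) -> str:
        return self.name[0]


class GenomeBuild:
    """Chromosome lengths + cytobands + deterministic pseudo-random sequence.

    Parameters
    ----------
    chromosomes:
        Ordered mapping chromosome name -> length in bp (> 0).
    cytobands:
        Optional list of :class:`Cytoband`. Bands must tile each chromosome
        they cover without overlap.
    seed:
        Seed for the synthetic sequence generator. Two builds with equal seed
        and lengths produce byte-identical sequence.
    """

    def __init__(
        self,
        chromosomes: dict[str, int],
        cytobands: list[Cytoband] | None = None,
        seed: int = 0,
    ):
        for name, length in chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        self.chromosomes: dict[str, int] = dict(chromosomes)
        self.seed = int(seed)
        self._bands: dict[str, list[Cytoband]] = {}
        for band in cytobands or []:
            self._bands.setdefault(band.chrom, []).append(band)
        for chrom, bands in self._bands.items():
            bands.sort(key=lambda b: b.start)
            prev_end = 0
            for b in bands:
                if b.start != prev_end + 1:
                    raise ValueError(
                        f"cytobands on {chrom} do not tile: gap/overlap at {b.start}"
                    )
                prev_end = b.end
            if chrom in self.chromosomes and prev_end != self.chromosomes[chrom]:
                raise ValueError(f"cytobands on {chrom} do not reach chromosome end")

    # -- coordinate helpers -------------------------------------------------

    def length(self, chrom: str) -> int:
        return self.chromosomes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    @property
    def cytobands(self) -> list[Cytoband]:
        return [b for bands in self._bands.values() for b in bands]

    def band_of(self, chrom: str, pos: int) -> Cytoband:
        for band in self._bands.get(chrom, []):
            if band.start <= pos <= band.end:
                return band
        raise KeyError(f"no cytoband covers {chrom}:{pos}")

    def arm_of(self, chrom: str, pos: int) -> str:
        """'p' or 'q' for a position, resolved from the cytoband table."""
        return self.band_of(chrom, pos).arm

    def band_span(self, chrom: str, start: int, end: int) -> str:
        """Band-span label in karyotype style, e.g. ``q32.1q37.3`` or ``q44``."""
        b1 = self.band_of(chrom, start).name
        b2 = self.band_of(chrom, end).name
        return b1 if b1 == b2 else b1 + b2

    # -- synthetic sequence -------------------------------------------------

    def _block(self, chrom: str, idx: int) -> np.ndarray:
        entropy = (self.seed, zlib.crc32(chrom.encode()), idx)
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))
        return _BASES[rng.integers(0, 4, size=_BLOCK)]

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Synthetic sequence of ``chrom`` over 1-based inclusive [start, end]."""
        if not 1 <= start <= end <= self.length(chrom):
            raise ValueError(f"[{start}, {end}] outside {chrom} (len {self.length(chrom)})")
        lo, hi = start - 1, end  # 0-based half-open
        parts = []
        for idx in range(lo // _BLOCK, (hi - 1) // _BLOCK + 1):
            block = self._block(chrom, idx)
            a = max(lo, idx * _BLOCK) - idx * _BLOCK
            b = min(hi, (idx + 1) * _BLOCK) - idx * _BLOCK
            parts.append(block[a:b])
        return np.concatenate(parts).tobytes().decode()


# ---------------------------------------------------------------------------
# Ready-made builds


def toy_genome(
    n_chromosomes: int = 4,
    lengths: tuple[int, ...] | None = None,
    p_fraction: float = 0.4,
    seed: int = 0,
) -> GenomeBuild:
    """Small desk-scale genome (default four 5-10 Mb chromosomes).

    Each chromosome gets three p bands (pter->cen: p13, p12, p11) and four
    q bands (q11, q12, q21, q22), the p arm covering ``p_fraction`` of the
    chromosome.
    """
    if lengths is None:
        lengths = tuple(5_000_000 + 1_250_000 * i for i in range(n_chromosomes))
    chroms = {f"chr{i + 1}": int(l) for i, l in enumerate(lengths)}
    bands: list[Cytoband] = []
    for chrom, length in chroms.items():
        cen = int(length * p_fraction)
        p_edges = np.linspace(0, cen, 4).astype(int)
        q_edges = np.linspace(cen, length, 5).astype(int)
        for name, lo, hi in zip(("p13", "p12", "p11"), p_edges[:-1], p_edges[1:]):
            bands.append(Cytoband(chrom, int(lo) + 1, int(hi), name))
        for name, lo, hi in zip(("q11", "q12", "q21", "q22"), q_edges[:-1], q_edges[1:]):
            bands.append(Cytoband(chrom, int(lo) + 1, int(hi), name))
    return GenomeBuild(chroms, bands, seed=seed)


#: GRCh37/hg19 chromosome lengths.
HG19_LENGTHS: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}

#: Approximate hg19 centromere positions (p/q boundary), bp.
HG19_CENTROMERES: dict[str, int] = {
    "chr1": 125000000, "chr2": 93300000, "chr3": 91000000, "chr4": 50400000,
    "chr5": 48400000, "chr6": 61000000, "chr7": 59900000, "chr8": 45600000,
    "chr9": 49000000, "chr10": 40200000, "chr11": 53700000, "chr12": 35800000,
    "chr13": 17900000, "chr14": 17600000, "chr15": 19000000, "chr16": 36600000,
    "chr17": 24000000, "chr18": 17200000, "chr19": 26500000, "chr20": 27500000,
    "chr21": 13200000, "chr22": 14700000, "chrX": 60600000, "chrY": 12500000,
}

# Curated hg19-style band boundaries for the chromosomes involved in the two
# bundled translocation cases. Only the bands needed to label those segments
# are subdivided; the remainder of each arm is lumped into flanking bands.
_HG19_CASE_BANDS: dict[str, list[tuple[int, int, str]]] = {
    # (1-based start, end, band)
    "chr1": [
        (1, 125000000, "p"),
        (125000001, 243700000, "q11q43"),
        (243700001, 249250621, "q44"),
    ],
    "chr2": [
        (1, 93300000, "p"),
        (93300001, 182100000, "q11.1q31.3"),
        (182100001, 188500000, "q32.1"),
        (188500001, 237300000, "q32.2q37.2"),
        (237300001, 243199373, "q37.3"),
    ],
    "chr12": [
        (1, 3300000, "p13.33"),
        (3300001, 5400000, "p13.32"),
        (5400001, 10000000, "p13.31"),
        (10000001, 35800000, "p13.2p11"),
        (35800001, 129300000, "q11q24.32"),
        (129300001, 133851895, "q24.33"),
    ],
    "chr14": [
        (1, 16100000, "p"),
        (16100001, 19100000, "q11.1"),
        (19100001, 64800000, "q11.2q23.2"),
        (64800001, 67900000, "q23.3"),
        (67900001, 104000000, "q24.1q32.32"),
        (104000001, 107349540, "q32.33"),
    ],
}


def hg19_genome(seed: int = 0) -> GenomeBuild:
    """Full-length hg19 build: real chromosome lengths, two-band (p/q) cytobands
    for most chromosomes, finer curated bands for chr1/2/12/14."""
    bands: list[Cytoband] = []
    for chrom, length in HG19_LENGTHS.items():
        if chrom in _HG19_CASE_BANDS:
            for start, end, name in _HG19_CASE_BANDS[chrom]:
                bands.append(Cytoband(chrom, start, end, name))
        else:
            cen = HG19_CENTROMERES[chrom]
            bands.append(Cytoband(chrom, 1, cen, "p"))
            bands.append(Cytoband(chrom, cen + 1, length, "q"))
    return GenomeBuild(dict(HG19_LENGTHS), bands, seed=seed)
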