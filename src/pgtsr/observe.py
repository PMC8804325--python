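"""Observation layers: SNP-array signals of a trophectoderm biopsy and
long-read split alignments of a carrier's genome.

The array model emulates whole-genome-amplification artifacts of a few-cell
biopsy: allele dropout (ADO) converts heterozygous truth to a homozygous
call, random miscalls flip the call class, and Gaussian noise dresses the
copy signal (log2 of copy number over 2) and the alt-allele fraction.

The read model treats reads as mapped coordinate intervals, not base
strings: a read drawn from a derivative chromosome that overlaps the
breakpoint junction maps back to the reference as a chimeric (split)
alignment with one segment per donor chromosome, split exactly at the
junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Embryo, Family, SNPPanel, embryo_truth_arrays
from .genome import GenomeBuild
from .translocation import DerivativeChromosome, Segment

# genotype call codes
NO_CALL, HOM_REF, HET, HOM_ALT = -1, 0, 1, 2
CALL_NAMES = {NO_CALL: "no_call", HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt"}


@dataclass
class ArrayObservation:
    """Per-SNP genotype calls and quantitative signals for one sample.

    Arrays are indexed like the panel: ``calls[chrom][i]`` is the call code
    at ``panel.positions[chrom][i]``. ``copy_signal`` is log2(copy/2)-like;
    ``allele_fraction`` in [0, 1] (NaN where the signal is undefined).
    """

    sample: str
    calls: dict[str, np.ndarray]
    copy_signal: dict[str, np.ndarray]
    allele_fraction: dict[str, np.ndarray]
    ado_rate: float = 0.0
    miscall_rate: float = 0.0
    signal_sd: float = 0.0
    seed: int = 0


def _call_from_counts(copy: np.ndarray, alt: np.ndarray) -> np.ndarray:
    call = np.full(len(copy), NO_CALL, dtype=np.int8)
    ok = copy > 0
    call[ok & (alt == 0)] = HOM_REF
    call[ok & (alt == copy)] = HOM_ALT
    call[ok & (alt > 0) & (alt < copy)] = HET
    return call


def emit_array(
    family: Family,
    panel: SNPPanel,
    embryo: Embryo,
    ado_rate: float = 0.0,
    miscall_rate: float = 0.0,
    signal_sd: float = 0.0,
    seed: int = 0,
) -> ArrayObservation:
    """Simulate the SNP-array observation of an embryo biopsy.

    Heterozygous truth drops one allele with probability ``ado_rate``
    (the surviving allele is equiprobably ref or alt); any call then flips
    to one of the other two classes with probability ``miscall_rate``.
    Copy signal and allele fraction carry Gaussian noise ``signal_sd``.
    """
    for rate in (ado_rate, miscall_rate):
        if not 0 <= rate < 1:
            raise ValueError("noise rates must be in [0, 1)")
    if panel.total_sites == 0:
        raise ValueError("empty SNP panel")
    rng = np.random.default_rng(seed)
    calls, sig, af = {}, {}, {}
    for chrom in panel.chromosomes:
        copy, alt, _ = embryo_truth_arrays(family, panel, embryo, chrom)
        call = _call_from_counts(copy, alt)

        het = call == HET
        dropped = het & (rng.random(len(call)) < ado_rate)
        survivor = np.where(rng.random(len(call)) < 0.5, HOM_REF, HOM_ALT)
        call = np.where(dropped, survivor, call).astype(np.int8)

        flip = (call != NO_CALL) & (rng.random(len(call)) < miscall_rate)
        # flip to one of the other two call classes, uniformly
        offset = rng.integers(1, 3, size=len(call))
        call = np.where(flip, (call + offset) % 3, call).astype(np.int8)

        with np.errstate(divide="ignore", invalid="ignore"):
            cs = np.where(copy > 0, np.log2(np.maximum(copy, 1) / 2.0), np.nan)
            frac = np.where(copy > 0, alt / np.maximum(copy, 1), np.nan)
        if signal_sd > 0:
            cs = cs + rng.normal(0, signal_sd, len(cs))
            frac = np.clip(frac + rng.normal(0, signal_sd, len(frac)), 0.0, 1.0)
        cs[copy == 0] = np.nan
        frac[copy == 0] = np.nan
        call[copy == 0] = NO_CALL
        calls[chrom], sig[chrom], af[chrom] = call, cs, frac
    return ArrayObservation(
        embryo.identifier, calls, sig, af, ado_rate, miscall_rate, signal_sd, seed
    )


def adult_observation(sample: str, genotypes: dict[str, np.ndarray]) -> ArrayObservation:
    """Noise-free disomic observation of an adult from dosage arrays (0/1/2)."""
    calls = {c: g.astype(np.int8) for c, g in genotypes.items()}
    sig = {c: np.zeros(len(g)) for c, g in genotypes.items()}
    af = {c: g / 2.0 for c, g in genotypes.items()}
    return ArrayObservation(sample, calls, sig, af)


# ---------------------------------------------------------------------------
# Long reads


@dataclass(frozen=True)
class AlignedSegment:
    """One aligned block of a read: reference interval + read-offset interval
    (both 1-based inclusive)."""

    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    read_start: int
    read_end: int


@dataclass
class SplitRead:
    """A mapped read; chimeric when it spans a junction (>= 2 segments)."""

    read_id: str
    segments: list[AlignedSegment]
    read_length: int

    def __post_init__(self):
        prev_end = 0
        for seg in self.segments:
            if seg.read_start <= prev_end:
                raise ValueError("read offsets must be increasing and non-overlapping")
            prev_end = seg.read_end

    @property
    def is_chimeric(self) -> bool:
        return len(self.segments) > 1


def _molecule_read(
    molecule: DerivativeChromosome, d_start: int, d_end: int, read_id: str
) -> SplitRead:
    """Map a molecule interval to reference segments (the read)."""
    segs = []
    for clipped, a, b in molecule.map_interval(d_start, d_end):
        segs.append(
            AlignedSegment(
                clipped.chrom,
                clipped.start,
                clipped.end,
                clipped.strand,
                a - d_start + 1,
                b - d_start + 1,
            )
        )
    return SplitRead(read_id, segs, d_end - d_start + 1)


def molecules_for_individual(
    genome: GenomeBuild,
    derivatives: tuple[DerivativeChromosome, DerivativeChromosome] | None,
    carrier: bool,
) -> list[DerivativeChromosome]:
    """The linear DNA molecules an individual contributes reads from.

    Every genome chromosome appears twice; a carrier replaces one homolog of
    each translocation chromosome with the corresponding derivative.
    """
    mols: list[DerivativeChromosome] = []
    replaced: set[str] = set()
    if carrier:
        if derivatives is None:
            raise ValueError("carrier requires derivative chromosomes")
        for der in derivatives:
            mols.append(der)
        # centromere-bearing donor chromosome of each derivative is replaced
        replaced = {der.name.strip("der()") for der in derivatives}
        replaced = {f"chr{x}" if not x.startswith("chr") else x for x in replaced}
    for chrom, length in genome.chromosomes.items():
        n_copies = 1 if chrom in replaced else 2
        for _ in range(n_copies):
            mols.append(DerivativeChromosome(chrom, [Segment(chrom, 1, length, "+")]))
    return mols


def emit_longreads(
    genome: GenomeBuild,
    molecules: list[DerivativeChromosome],
    n_reads: int,
    mean_len: float = 16_679.0,
    seed: int = 0,
) -> list[SplitRead]:
    """Draw ``n_reads`` reads: molecule chosen proportional to length, start
    uniform, length geometric with the given mean (nanopore-scale default),
    truncated at the molecule end."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if mean_len <= 0:
        raise ValueError("mean_len must be positive")
    rng = np.random.default_rng(seed)
    lengths = np.array([m.total_length for m in molecules], dtype=float)
    probs = lengths / lengths.sum()
    reads = []
    choices = rng.choice(len(molecules), size=n_reads, p=probs)
    for i, mi in enumerate(choices):
        mol = molecules[mi]
        start = int(rng.integers(1, mol.total_length + 1))
        length = int(rng.geometric(1.0 / mean_len))
        end = min(start + length - 1, mol.total_length)
        reads.append(_molecule_read(mol, start, end, f"read{i:06d}"))
    return reads


def plant_junction_reads(
    derivative: DerivativeChromosome,
    n_reads: int,
    read_len: int = 10_000,
    min_overlap: int = 200,
    jitter: int = 0,
    seed: int = 0,
    id_prefix: str = "plant",
) -> list[SplitRead]:
    """Plant reads guaranteed to span the junction of one derivative.

    Each read covers at least ``min_overlap`` bases on both sides of the
    junction. ``jitter`` shifts each aligned segment's reported reference
    coordinates by a uniform integer in [-jitter, jitter], emulating
    alignment imprecision near the breakend.
    """
    rng = np.random.default_rng(seed)
    jo = derivative.junction_offset
    ins = len(derivative.insertion)
    lo = max(1, jo + ins + min_overlap - read_len + 1)
    hi = min(jo - min_overlap + 1, derivative.total_length - read_len + 1)
    if hi < lo:
        raise ValueError("read_len too short to span the junction with min_overlap")
    out = []
    for i in range(n_reads):
        start = int(rng.integers(lo, hi + 1))
        read = _molecule_read(derivative, start, start + read_len - 1, f"{id_prefix}{i:04d}")
        if jitter:
            segs = []
            for seg in read.segments:
                d = int(rng.integers(-jitter, jitter + 1))
                segs.append(
                    AlignedSegment(
                        seg.chrom, seg.ref_start + d, seg.ref_end + d,
                        seg.strand, seg.read_start, seg.read_end,
                    )
                )
            read = SplitRead(read.read_id, segs, read.read_length)
        out.append(read)
    return out
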