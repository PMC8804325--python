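"""File formats: genome/cytoband TSV, split-read TSV, gene BED, SV-database
TSV, primer TSV, FASTA, and VCF (multi-sample GT and breakend calls).

Coordinates follow each format's native convention: BED and UCSC cytoband
files are 0-based half-open, everything else is 1-based inclusive (the
package's internal convention). VCF is written as plain v4.2 text and read
back with cyvcf2.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import Cytoband, GenomeBuild
from .jpcr import PrimerPair
from .observe import NO_CALL, AlignedSegment, ArrayObservation, SplitRead
from .svcall import GeneInterval, GeneModel, SVDatabaseRecord, TranslocationCall

# -- genome build -----------------------------------------------------------


def write_genome_tsv(genome: GenomeBuild, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chromosomes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_genome_tsv(path: str, cytoband_path: str | None = None, seed: int = 0) -> GenomeBuild:
    chroms: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, length = line.split("\t")
                chroms[chrom] = int(length)
    bands = read_cytoband_tsv(cytoband_path) if cytoband_path else None
    return GenomeBuild(chroms, bands, seed=seed)


def write_cytoband_tsv(bands: Iterable[Cytoband], path: str) -> None:
    """UCSC cytoBand dialect: 0-based half-open."""
    with open(path, "w") as fh:
        for b in bands:
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\t{b.name}\n")


def read_cytoband_tsv(path: str) -> list[Cytoband]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            out.append(Cytoband(chrom, int(start) + 1, int(end), name))
    return out


# -- split reads ------------------------------------------------------------

_READS_COLUMNS = [
    "read_id", "segment_index", "chrom", "ref_start", "ref_end",
    "strand", "read_start", "read_end",
]


def write_reads_tsv(reads: Iterable[SplitRead], path: str) -> None:
    rows = []
    for read in reads:
        for i, seg in enumerate(read.segments):
            rows.append(
                (read.read_id, i, seg.chrom, seg.ref_start, seg.ref_end,
                 seg.strand, seg.read_start, seg.read_end)
            )
    pd.DataFrame(rows, columns=_READS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str) -> list[SplitRead]:
    df = pd.read_csv(path, sep="\t")
    reads = []
    for read_id, grp in df.groupby("read_id", sort=False):
        grp = grp.sort_values("segment_index")
        segs = [
            AlignedSegment(r.chrom, int(r.ref_start), int(r.ref_end),
                           r.strand, int(r.read_start), int(r.read_end))
            for r in grp.itertuples()
        ]
        reads.append(SplitRead(str(read_id), segs, int(grp["read_end"].max())))
    return reads


# -- genes and SV databases -------------------------------------------------


def read_genes_bed(path: str) -> GeneModel:
    """BED (0-based half-open); column 4 is the gene symbol, column 6 the
    strand when present."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "+"
            intervals.append(GeneInterval(f[0], int(f[1]) + 1, int(f[2]), strand, f[3]))
    return GeneModel(intervals)


def write_genes_bed(intervals: Iterable[GeneInterval], path: str) -> None:
    with open(path, "w") as fh:
        for g in intervals:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


def read_svdb_tsv(path: str) -> list[SVDatabaseRecord]:
    """BED-like TSV with a type column:
    ``chrom  start  end  type  source  [chrom2  pos2]`` (1-based here)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom2 = f[5] if len(f) > 6 else None
            pos2 = int(f[6]) if len(f) > 6 else None
            out.append(
                SVDatabaseRecord(f[3], f[0], int(f[1]), int(f[2]), f[4], chrom2, pos2)
            )
    return out


# -- primers ----------------------------------------------------------------


def read_primers_tsv(path: str) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        PrimerPair(r.assay, r.forward, r.reverse, int(r.expected_size))
        for r in df.itertuples()
    ]


def write_primers_tsv(pairs: Iterable[PrimerPair], path: str) -> None:
    pd.DataFrame(
        [(p.assay, p.forward, p.reverse, p.expected_size) for p in pairs],
        columns=["assay", "forward", "reverse", "expected_size"],
    ).to_csv(path, sep="\t", index=False)


# -- FASTA ------------------------------------------------------------------


def write_fasta(records: dict[str, str], path: str, width: int = 80) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    seqio_write(recs, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# -- VCF --------------------------------------------------------------------

_GT_STRINGS = {NO_CALL: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_genotypes_vcf(
    positions: dict[str, np.ndarray],
    samples: dict[str, dict[str, np.ndarray]],
    genome: GenomeBuild,
    path: str,
) -> None:
    """Multi-sample VCF v4.2 with GT only.

    ``samples`` maps sample name -> {chrom: call-code array} aligned with
    ``positions``. Panel sites are abstract bi-allelic markers; REF/ALT are
    written as A/G placeholders.
    """
    names = list(samples)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in genome.chromosomes.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        for chrom, pos in positions.items():
            for i, p in enumerate(pos):
                gts = "\t".join(_GT_STRINGS[int(samples[s][chrom][i])] for s in names)
                fh.write(f"{chrom}\t{int(p)}\tsnp_{chrom}_{i}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_genotypes_vcf(path: str) -> tuple[dict[str, np.ndarray], dict[str, dict[str, np.ndarray]]]:
    """Read a GT VCF back into (positions, sample -> chrom -> call codes)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    names = list(vcf.samples)
    positions: dict[str, list[int]] = {}
    calls: dict[str, dict[str, list[int]]] = {s: {} for s in names}
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    remap = {0: 0, 1: 1, 3: 2, 2: NO_CALL}
    for var in vcf:
        positions.setdefault(var.CHROM, []).append(var.POS)
        for s, gt in zip(names, var.gt_types):
            calls[s].setdefault(var.CHROM, []).append(remap[int(gt)])
    pos_arr = {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()}
    call_arr = {
        s: {c: np.asarray(v, dtype=np.int8) for c, v in chroms.items()}
        for s, chroms in calls.items()
    }
    return pos_arr, call_arr


_BND_BRACKETS = {
    # (this side's orientation, partner orientation) -> ALT template
    ("R", "L"): "N[{chrom}:{pos}[",
    ("R", "R"): "N]{chrom}:{pos}]",
    ("L", "L"): "[{chrom}:{pos}[N",
    ("L", "R"): "]{chrom}:{pos}]N",
}


def write_calls_vcf(calls: list[TranslocationCall], genome: GenomeBuild, path: str) -> None:
    """Minimal breakend (SVTYPE=BND) VCF for translocation calls; each call
    writes its two mated breakend records."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Spanning reads">\n')
        fh.write('##FILTER=<ID=low_support,Description="Fewer spanning reads than required">\n')
        for chrom, length in genome.chromosomes.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, call in enumerate(calls):
            flt = "PASS" if call.passed else "low_support"
            for side, (chrom, pos, orient, pchrom, ppos, porient) in enumerate(
                [
                    (call.chromA, call.posA, call.orientA, call.chromB, call.posB, call.orientB),
                    (call.chromB, call.posB, call.orientB, call.chromA, call.posA, call.orientA),
                ]
            ):
                alt = _BND_BRACKETS[(orient, porient)].format(chrom=pchrom, pos=ppos)
                mate = f"bnd_{i}_{1 - side}"
                fh.write(
                    f"{chrom}\t{pos}\tbnd_{i}_{side}\tN\t{alt}\t.\t{flt}\t"
                    f"SVTYPE=BND;MATEID={mate};SUPPORT={call.support}\n"
                )


def write_calls_tsv(calls: list[TranslocationCall], path: str) -> None:
    pd.DataFrame(
        [
            (c.chromA, c.posA, c.orientA, c.chromB, c.posB, c.orientB, c.support, c.filter)
            for c in calls
        ],
        columns=["chromA", "posA", "orientA", "chromB", "posB", "orientB", "support", "filter"],
    ).to_csv(path, sep="\t", index=False)


# -- array observations -----------------------------------------------------


def write_array_tsv(obs: ArrayObservation, positions: dict[str, np.ndarray], path: str) -> None:
    rows = []
    for chrom, pos in positions.items():
        for i, p in enumerate(pos):
            rows.append(
                (chrom, int(p), int(obs.calls[chrom][i]),
                 float(obs.copy_signal[chrom][i]), float(obs.allele_fraction[chrom][i]))
            )
    pd.DataFrame(
        rows, columns=["chrom", "position", "call", "copy_signal", "allele_fraction"]
    ).to_csv(path, sep="\t", index=False, float_format="%.5f")


def read_array_tsv(path: str, sample: str = "sample") -> tuple[dict[str, np.ndarray], ArrayObservation]:
    df = pd.read_csv(path, sep="\t")
    positions, calls, sig, af = {}, {}, {}, {}
    for chrom, grp in df.groupby("chrom", sort=False):
        positions[chrom] = grp["position"].to_numpy(np.int64)
        calls[chrom] = grp["call"].to_numpy(np.int8)
        sig[chrom] = grp["copy_signal"].to_numpy(float)
        af[chrom] = grp["allele_fraction"].to_numpy(float)
    return positions, ArrayObservation(sample, calls, sig, af)
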