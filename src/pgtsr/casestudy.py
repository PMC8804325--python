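"""Bundled worked example: two reciprocal-translocation carrier families.

This module is a reconstruction from the printed results of a clinical
PGT-SR case series (no raw data were deposited): two carrier couples,
twelve biopsied blastocysts, with each embryo's molecular karyotype,
junction-spanning PCR signs, breakpoint-region haplotype verdicts, and the
recombination blocks observed along the translocation chromosomes. It
exists to pin the decision logic of the pipeline against known verdicts;
it is not raw data.

Family 1 — 46,XX,t(1;2)(q44;q32.1)mat, breakpoints chr1:244,573,198 and
chr2:182,319,607 (22 spanning long reads); family 2 —
46,XY,t(12;14)(p13.31;q23.3)pat, breakpoints chr12:5,959,384 and
chr14:66,307,382 (17 spanning reads). Junction insertions in the series
were under 40 bases; their exact sequences were not printed and are left
empty here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .translocation import TranslocationSpec


@dataclass(frozen=True)
class RecombinationBlock:
    """One printed haplotype block on a translocation chromosome."""

    embryo: str
    chrom: str
    start: int
    end: int
    n_snps: int


@dataclass(frozen=True)
class CaseEmbryo:
    name: str
    karyotype: str  # molecular karyotype string
    der_a_pcr: bool  # junction assay of der(A)
    der_b_pcr: bool
    region_a: str  # haplotype verdict of breakpoint region A
    region_b: str
    status: str  # carrier | normal | unbalanced (the confirmed verdict)

    @property
    def cnv_balanced(self) -> bool:
        return self.karyotype == "(1–22)*1,(XN)*1"


@dataclass(frozen=True)
class CaseFamily:
    name: str
    spec: TranslocationSpec
    supporting_reads: int
    reference: str  # phasing reference relative
    embryos: tuple[CaseEmbryo, ...]
    recombination_blocks: tuple[RecombinationBlock, ...] = ()
    informative_in_region: dict[str, tuple[int, int]] = field(default_factory=dict)


FAMILY_1 = CaseFamily(
    name="family1",
    spec=TranslocationSpec("chr1", 244_573_198, "chr2", 182_319_607, armA="q", armB="q"),
    supporting_reads=22,
    reference="grandmother",
    embryos=(
        CaseEmbryo("Embryo-1", "1q44*1; 2q32.1q37.3*3", True, False, "derivative", "normal", "unbalanced"),
        CaseEmbryo("Embryo-2", "1q44*3; 2q32.1q37.3*1", False, True, "normal", "derivative", "unbalanced"),
        CaseEmbryo("Embryo-3", "(1–22)*1,(XN)*1", True, True, "derivative", "derivative", "carrier"),
        CaseEmbryo("Embryo-4", "(1–22)*1,(XN)*1", False, False, "normal", "normal", "normal"),
        CaseEmbryo("Embryo-5", "(1–22)*1,(XN)*1", False, False, "normal", "normal", "normal"),
        CaseEmbryo("Embryo-6", "(1–22)*1,(XN)*1", False, False, "normal", "normal", "normal"),
    ),
    recombination_blocks=(
        RecombinationBlock("Embryo-3", "chr1", 1, 12_186_274, 127),
        RecombinationBlock("Embryo-3", "chr1", 48_083_274, 107_951_986, 423),
        RecombinationBlock("Embryo-3", "chr2", 27_807_350, 65_522_654, 341),
        RecombinationBlock("Embryo-3", "chr2", 193_324_405, 234_037_544, 328),
        RecombinationBlock("Embryo-4", "chr1", 34_419_776, 163_565_845, 828),
        RecombinationBlock("Embryo-4", "chr1", 205_474_838, 231_902_291, 226),
        RecombinationBlock("Embryo-4", "chr1", 245_135_196, 249_250_621, 44),
        RecombinationBlock("Embryo-4", "chr2", 102_068_311, 131_602_187, 196),
        RecombinationBlock("Embryo-4", "chr2", 193_324_405, 243_199_373, 335),
        RecombinationBlock("Embryo-5", "chr1", 38_670_335, 82_095_444, 503),
        RecombinationBlock("Embryo-5", "chr1", 156_883_028, 201_751_539, 264),
        RecombinationBlock("Embryo-5", "chr2", 1, 66_217_787, 648),
        RecombinationBlock("Embryo-5", "chr2", 240_229_300, 243_199_373, 24),
        RecombinationBlock("Embryo-6", "chr1", 1, 65_798_457, 649),
        RecombinationBlock("Embryo-6", "chr2", 23_021_659, 64_943_105, 366),
        RecombinationBlock("Embryo-6", "chr2", 222_699_721, 243_199_373, 171),
    ),
    # informative SNPs (in 2 Mb region, chromosome-wide) per diploid embryo/chrom
    informative_in_region={
        "Embryo-3/chr1": (18, 1694), "Embryo-3/chr2": (4, 1770),
        "Embryo-4/chr1": (18, 1681), "Embryo-4/chr2": (3, 1722),
        "Embryo-5/chr1": (18, 1666), "Embryo-5/chr2": (4, 1750),
        "Embryo-6/chr1": (15, 1625), "Embryo-6/chr2": (4, 1662),
    },
)

FAMILY_2 = CaseFamily(
    name="family2",
    spec=TranslocationSpec("chr12", 5_959_384, "chr14", 66_307_382, armA="p", armB="q"),
    supporting_reads=17,
    reference="grandfather",
    embryos=(
        CaseEmbryo("Embryo-1", "12p13.33p13.31*3; 14q23.3q32.33*1", False, True, "normal", "derivative", "unbalanced"),
        CaseEmbryo("Embryo-2", "(1–22)*1,(XN)*1", True, True, "derivative", "derivative", "carrier"),
        CaseEmbryo("Embryo-3", "12p13.33p13.31*3; 14q23.3q32.33*1", False, True, "normal", "derivative", "unbalanced"),
        CaseEmbryo("Embryo-4", "12p13.31q24.33*1; 14q11.1q23.3*3", False, True, "normal", "derivative", "unbalanced"),
        CaseEmbryo("Embryo-5", "(1–22)*1,(XN)*1", True, True, "derivative", "derivative", "carrier"),
        # region B printed as "Negative" in the source table (neither
        # Derivative nor Normal); treated as no informative signal for a
        # region lost from the embryo
        CaseEmbryo("Embryo-6", "12p13.33p13.31*1; 14q23.3q32.33*3", True, False, "derivative", "ambiguous", "unbalanced"),
    ),
    recombination_blocks=(
        RecombinationBlock("Embryo-2", "chr12", 1, 2_019_430, 14),
        RecombinationBlock("Embryo-2", "chr12", 25_776_583, 133_851_895, 812),
        RecombinationBlock("Embryo-2", "chr14", 1, 29_117_385, 94),
        RecombinationBlock("Embryo-5", "chr12", 1, 3_538_270, 30),
        RecombinationBlock("Embryo-5", "chr12", 43_737_510, 133_851_895, 679),
        RecombinationBlock("Embryo-5", "chr14", 96_027_947, 107_349_540, 87),
    ),
    informative_in_region={
        "Embryo-2/chr12": (22, 890), "Embryo-2/chr14": (20, 671),
        "Embryo-5/chr12": (25, 997), "Embryo-5/chr14": (20, 722),
    },
)

CASE_FAMILIES: tuple[CaseFamily, ...] = (FAMILY_1, FAMILY_2)
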