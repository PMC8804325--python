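"""Family-haplotype linkage analysis of translocation breakpoint regions.

An informative SNP is heterozygous in the carrier and homozygous in the
spouse (and in the phasing reference), so the allele the embryo inherited
from the carrier is always resolvable: a heterozygous embryo call implies
the carrier transmitted the non-spouse allele; a homozygous call implies
the carrier transmitted that allele.

Phasing labels the carrier's two haplotypes "derivative" (riding der(A) and
der(B)) and "normal". Two references are supported:

* the transmitting grandparent — the carrier's own carrier parent: at an
  informative SNP where the grandparent is homozygous, the carrier allele
  matching it was inherited from that grandparent and therefore lies on the
  derivative haplotype;
* an unbalanced embryo with known retained structural content: where the
  carrier's contribution to the embryo comes through exactly one element,
  the embryo's carrier-inherited allele reveals that haplotype directly.

A breakpoint-region call is a majority vote of the phased informative SNPs
within breakpoint ± half-width (2 Mb total by default); a chromosome-wide
scan for sustained haplotype switches locates meiotic recombination events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import DER_A, DER_B, Gamete, HAP_N, HAP_T
from .genome import GenomeBuild
from .observe import HET, HOM_ALT, HOM_REF, NO_CALL

DEFAULT_HALF_WIDTH = 1_000_000  # "2 Mb region" = breakpoint ± 1 Mb
DEFAULT_MIN_VOTES = 3
DEFAULT_PERSISTENCE = 3  # consecutive SNPs to accept a haplotype switch
MENDEL_TOLERANCE = 0.05


@dataclass(frozen=True)
class InformativeSNP:
    """A phased marker: which allele rides the derivative haplotype."""

    chrom: str
    position: int
    index: int  # panel site index
    spouse_allele: int
    derivative_allele: int
    normal_allele: int


def _is_hom(call: int) -> bool:
    return call in (HOM_REF, HOM_ALT)


def _hom_allele(call: int) -> int:
    return 0 if call == HOM_REF else 1


def select_informative(
    chrom: str,
    positions: np.ndarray,
    carrier_calls: np.ndarray,
    spouse_calls: np.ndarray,
    reference_calls: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of sites heterozygous in the carrier, homozygous in the
    spouse (and, when given, homozygous in the reference; missing reference
    genotypes skip the site)."""
    ok = (carrier_calls == HET) & ((spouse_calls == HOM_REF) | (spouse_calls == HOM_ALT))
    if reference_calls is not None:
        ok &= (reference_calls == HOM_REF) | (reference_calls == HOM_ALT)
    return np.flatnonzero(ok)


def phase_with_grandparent(
    chrom: str,
    positions: np.ndarray,
    carrier_calls: np.ndarray,
    spouse_calls: np.ndarray,
    grandparent_calls: np.ndarray,
) -> list[InformativeSNP]:
    """Phase against the transmitting grandparent: the carrier allele
    matching the grandparent's homozygous genotype is the derivative one."""
    out = []
    for i in select_informative(chrom, positions, carrier_calls, spouse_calls, grandparent_calls):
        g = _hom_allele(int(grandparent_calls[i]))
        out.append(
            InformativeSNP(
                chrom, int(positions[i]), int(i),
                _hom_allele(int(spouse_calls[i])),
                derivative_allele=g, normal_allele=1 - g,
            )
        )
    return out


def carrier_allele_from_call(call: int, spouse_allele: int) -> int | None:
    """The allele the carrier transmitted, given the embryo's call and the
    spouse's homozygous allele (None when the call is missing)."""
    if call == NO_CALL:
        return None
    if call == HET:
        return 1 - spouse_allele
    return _hom_allele(call)


def phase_with_embryo(
    chrom: str,
    positions: np.ndarray,
    carrier_calls: np.ndarray,
    spouse_calls: np.ndarray,
    embryo_calls: np.ndarray,
    embryo_gamete: Gamete,
) -> list[InformativeSNP]:
    """Phase against an unbalanced embryo of known structural content.

    Only sites where the carrier's contribution passes through exactly one
    gamete element are phased: the carrier-inherited allele then reveals the
    haplotype of that element (derivative -> HAP_T, normal -> HAP_N).
    """
    pieces = [p for p in embryo_gamete.pieces if p.chrom == chrom]
    out = []
    for i in select_informative(chrom, positions, carrier_calls, spouse_calls):
        pos = int(positions[i])
        cover = [p for p in pieces if p.start <= pos <= p.end]
        if len(cover) != 1:
            continue
        s = _hom_allele(int(spouse_calls[i]))
        allele = carrier_allele_from_call(int(embryo_calls[i]), s)
        if allele is None:
            continue
        if cover[0].hap == HAP_T:
            der, norm = allele, 1 - allele
        else:
            der, norm = 1 - allele, allele
        out.append(InformativeSNP(chrom, pos, int(i), s, der, norm))
    return out


# ---------------------------------------------------------------------------
# Region calls


@dataclass
class RegionCall:
    """Majority-vote haplotype call for one breakpoint region."""

    chrom: str
    breakpoint: int
    half_width: int
    votes_derivative: int
    votes_normal: int
    no_calls: int
    verdict: str  # derivative | normal | ambiguous

    @property
    def n_votes(self) -> int:
        return self.votes_derivative + self.votes_normal


def region_call(
    embryo_calls: np.ndarray,
    phased: list[InformativeSNP],
    breakpoint: int,
    half_width: int = DEFAULT_HALF_WIDTH,
    min_votes: int = DEFAULT_MIN_VOTES,
) -> RegionCall:
    """Vote the phased informative SNPs within breakpoint ± ``half_width``.

    Each marker's carrier-inherited embryo allele votes derivative or
    normal; the verdict needs a strict majority over at least ``min_votes``
    total votes, otherwise it is ambiguous.
    """
    votes_d = votes_n = missing = 0
    chrom = phased[0].chrom if phased else "?"
    for snp in phased:
        if not breakpoint - half_width <= snp.position <= breakpoint + half_width:
            continue
        allele = carrier_allele_from_call(int(embryo_calls[snp.index]), snp.spouse_allele)
        if allele is None:
            missing += 1
        elif allele == snp.derivative_allele:
            votes_d += 1
        else:
            votes_n += 1
    total = votes_d + votes_n
    if total >= min_votes and votes_d != votes_n:
        verdict = "derivative" if votes_d > votes_n else "normal"
    else:
        verdict = "ambiguous"
    return RegionCall(chrom, breakpoint, half_width, votes_d, votes_n, missing, verdict)


# ---------------------------------------------------------------------------
# Recombination scan


@dataclass
class RecombinationEvent:
    """A sustained haplotype switch along one chromosome."""

    chrom: str
    start: int  # last concordant SNP before the switch
    end: int  # first SNP of the sustained switched run
    n_snps: int  # SNPs in the switched block
    band_span: str = ""
    in_breakpoint_region: bool = False


def recombination_scan(
    embryo_calls: np.ndarray,
    phased: list[InformativeSNP],
    persistence: int = DEFAULT_PERSISTENCE,
    breakpoints: list[int] = (),
    genome: GenomeBuild | None = None,
) -> list[RecombinationEvent]:
    """Locate haplotype switches sustained over >= ``persistence`` SNPs.

    The embryo's carrier-inherited allele at each phased marker maps to a
    haplotype label (derivative/normal); runs shorter than ``persistence``
    are treated as ADO/miscall noise. Each event's interval spans from the
    last marker of the previous sustained run to the first marker of the
    next; the flag marks an event that straddles a breakpoint (see
    :func:`recombination_in_breakpoint_region`).
    """
    markers = sorted(phased, key=lambda s: s.position)
    labels, pos = [], []
    for snp in markers:
        allele = carrier_allele_from_call(int(embryo_calls[snp.index]), snp.spouse_allele)
        if allele is None:
            continue
        labels.append(1 if allele == snp.derivative_allele else 0)
        pos.append(snp.position)
    if len(labels) < persistence:
        warnings.warn("fewer phased markers than the persistence threshold; no scan")
        return []
    # compress into runs, keep sustained runs as anchors
    runs = []  # (label, first_idx, last_idx)
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i - 1))
            start = i
    anchors = [r for r in runs if r[2] - r[1] + 1 >= persistence]
    events = []
    chrom = markers[0].chrom if markers else "?"
    for prev, nxt in zip(anchors, anchors[1:]):
        if prev[0] == nxt[0]:
            continue
        lo, hi = pos[prev[2]], pos[nxt[1]]
        flag = recombination_in_breakpoint_region(lo, hi, breakpoints)
        span = ""
        if genome is not None:
            try:
                span = genome.band_span(chrom, lo, hi)
            except KeyError:
                pass
        events.append(
            RecombinationEvent(chrom, lo, hi, nxt[2] - nxt[1] + 1, span, flag)
        )
    return events


def recombination_in_breakpoint_region(start: int, end: int, breakpoints: list[int]) -> bool:
    """Whether a recombination interval disrupts breakpoint-junction linkage.

    An event (or reported haplotype block) counts as "in the breakpoint
    region" when its interval straddles the breakpoint itself — the
    haplotype phase then switches across the junction and the
    breakpoint-adjacent markers no longer track the derivative. A crossover
    that merely reaches into the flanking region leaves the junction-adjacent
    linkage intact; such cases surface as mixed region votes (ambiguous
    verdicts) rather than through this flag.
    """
    return any(start <= bp <= end for bp in breakpoints)


# ---------------------------------------------------------------------------
# Integrated classification


@dataclass
class EmbryoClassification:
    """Integrated verdict for one embryo with per-evidence provenance."""

    embryo: str
    region_a: str
    region_b: str
    ccs_status: str  # balanced | unbalanced
    comprehensive: str  # carrier | normal | unbalanced | ambiguous
    pcr_class: str | None = None

    @property
    def concordant(self) -> bool | None:
        if self.pcr_class is None:
            return None
        return self.pcr_class == self.comprehensive


def linkage_classify(
    embryo: str,
    call_a: RegionCall,
    call_b: RegionCall,
    ccs_status: str,
    pcr_class: str | None = None,
) -> EmbryoClassification:
    """Combine the two breakpoint-region calls with the CCS verdict.

    An unbalanced CCS dominates (the region calls then document which
    derivative is retained); under a balanced CCS, two derivative calls
    mean carrier, two normal calls mean normal, and anything mixed or
    ambiguous is flagged for review (possible recombination inside a
    breakpoint region).
    """
    va, vb = call_a.verdict, call_b.verdict
    if ccs_status == "unbalanced":
        comprehensive = "unbalanced"
    elif va == vb == "derivative":
        comprehensive = "carrier"
    elif va == vb == "normal":
        comprehensive = "normal"
    else:
        warnings.warn(
            f"embryo {embryo}: region verdicts ({va}, {vb}) under balanced CCS; "
            "possible recombination inside a breakpoint region"
        )
        comprehensive = "ambiguous"
    return EmbryoClassification(embryo, va, vb, ccs_status, comprehensive, pcr_class)


def mendelian_error_fraction(
    carrier_calls: np.ndarray, spouse_calls: np.ndarray, embryo_calls: np.ndarray
) -> float:
    """Fraction of called disomic-model sites where the embryo's genotype is
    incompatible with Mendelian transmission from the couple (an allele
    absent from a parent who must have transmitted it). Above
    MENDEL_TOLERANCE the sample should be treated as a failed WGA."""

    def transmissible(call: int) -> set[int]:
        if call == HET:
            return {0, 1}
        return {_hom_allele(call)}

    n = bad = 0
    for c, s, e in zip(carrier_calls, spouse_calls, embryo_calls):
        if NO_CALL in (int(c), int(s), int(e)):
            continue
        n += 1
        tc, ts = transmissible(int(c)), transmissible(int(s))
        if int(e) == HET:
            ok = (0 in tc and 1 in ts) or (1 in tc and 0 in ts)
        else:
            x = _hom_allele(int(e))
            ok = x in tc and x in ts
        if not ok:
            bad += 1
    return bad / n if n else 0.0
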