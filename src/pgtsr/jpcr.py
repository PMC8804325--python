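"""In-silico junction-spanning PCR.

A junction assay's primers flank the breakpoint junction of one derivative
chromosome, so a product forms only when that derivative is present in the
sample; reference assays amplify across the intact breakpoint position of
the normal chromosome. Comparing the der(A) and der(B) junction assays with
the copy-number verdict classifies an embryo:

=========  =========  ============  ====================
der(A)     der(B)     CNV balanced  class
=========  =========  ============  ====================
positive   positive   yes           carrier
negative   negative   yes           normal
one positive, one negative          unbalanced
positive   positive   no            conflict (review)
negative   negative   no            conflict (review)
=========  =========  ============  ====================

Primer matching is exact string matching on the plus strand of a template
(thermodynamics are out of scope); the product size is the distance between
the two primers' 5' ends on the template, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import reverse_complement

from .cohort import DER_A, DER_B, NORMAL_A, NORMAL_B
from .genome import GenomeBuild
from .translocation import DerivativeChromosome

DEFAULT_MAX_PRODUCT = 2000  # bp, gel-verifiable scale


@dataclass(frozen=True)
class PrimerPair:
    """A PCR assay: forward and reverse primers (5'->3') + expected size."""

    assay: str
    forward: str
    reverse: str
    expected_size: int

    def __post_init__(self):
        if not self.forward or not self.reverse:
            raise ValueError("primer sequences must be non-empty")
        if self.expected_size <= len(self.forward) + len(self.reverse):
            raise ValueError("expected product size must exceed the primers' total length")


@dataclass
class AmpliconResult:
    """Outcome of in-silico PCR of one assay on one template."""

    assay: str
    present: bool
    size: int | None = None
    start: int | None = None  # 1-based template offset of the forward 5' end
    end: int | None = None  # 1-based template offset of the reverse 5' end
    ambiguous: bool = False
    all_sizes: list[int] = field(default_factory=list)


@dataclass
class JunctionTemplate:
    """Junction-spanning template: ``flank`` bases from the donor upstream of
    the junction, the insertion, and ``flank`` bases downstream."""

    derivative_name: str
    sequence: str
    flank: int
    insertion_length: int
    _derivative: DerivativeChromosome
    _d_start: int  # derivative coordinate of template offset 1

    def ref_coord(self, offset: int) -> tuple[str | None, int, str]:
        """Map template offset (1-based) to (chrom, position, strand); the
        insertion maps to (None, index-within-insertion, '+')."""
        if not 1 <= offset <= len(self.sequence):
            raise ValueError(f"offset {offset} outside template")
        return self._derivative.ref_coord(self._d_start + offset - 1)


def junction_template(
    derivative: DerivativeChromosome, genome: GenomeBuild, flank: int
) -> JunctionTemplate:
    """Extract the junction-spanning template of a derivative chromosome."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    jo = derivative.junction_offset
    ins = len(derivative.insertion)
    if flank > jo or jo + ins + flank > derivative.total_length:
        raise ValueError("flank exceeds the available segment on one side of the junction")
    d_start = jo - flank + 1
    seq = derivative.sequence(genome, d_start, jo + ins + flank)
    return JunctionTemplate(derivative.name, seq, flank, ins, derivative, d_start)


def reference_template(genome: GenomeBuild, chrom: str, pos: int, flank: int) -> str:
    """Template across the intact breakpoint position of a normal chromosome."""
    lo, hi = max(1, pos - flank + 1), min(genome.length(chrom), pos + flank)
    return genome.sequence(chrom, lo, hi)


def insilico_pcr(
    template: str, pair: PrimerPair, max_product: int = DEFAULT_MAX_PRODUCT
) -> AmpliconResult:
    """Exact-match PCR on the plus strand of one template.

    A product exists when the forward primer matches the plus strand and the
    reverse complement of the reverse primer matches downstream, the 5'-to-5'
    distance not exceeding ``max_product``. The smallest product is reported;
    more than one product flags the result ambiguous.
    """
    if max_product <= 0:
        raise ValueError("max_product must be positive")
    fwd, rev_rc = pair.forward.upper(), reverse_complement(pair.reverse.upper())
    template = template.upper()

    def occurrences(needle: str) -> list[int]:
        out, i = [], template.find(needle)
        while i != -1:
            out.append(i)
            i = template.find(needle, i + 1)
        return out

    f_sites = occurrences(fwd)
    r_sites = occurrences(rev_rc)
    products = []
    for i in f_sites:
        for j in r_sites:
            if j < i + len(fwd):
                continue  # reverse site must lie downstream of the forward primer
            size = j + len(rev_rc) - i  # 5' start to 5' start, inclusive
            if size <= max_product:
                products.append((size, i + 1, j + len(rev_rc)))
    if not products:
        return AmpliconResult(pair.assay, present=False)
    products.sort()
    size, start, end = products[0]
    return AmpliconResult(
        pair.assay, True, size, start, end,
        ambiguous=len(products) > 1, all_sizes=[p[0] for p in products],
    )


def design_junction_primers(
    derivative: DerivativeChromosome,
    genome: GenomeBuild,
    k: int = 20,
    min_gap: int = 50,
    flank: int = 600,
    other_templates: list[str] = (),
) -> PrimerPair:
    """Convenience junction-primer picker (not a thermodynamic design tool):
    the first ``k``-mer at least ``min_gap`` bases upstream of the junction
    that is unique in the supplied templates, and likewise downstream.
    User-supplied primers always take precedence over this picker.
    """
    tpl = junction_template(derivative, genome, flank)
    seq = tpl.sequence
    jo_t = tpl.flank  # template offset of the junction (end of upstream flank)

    def unique(sub: str) -> bool:
        hay = [seq] + list(other_templates)
        rc = reverse_complement(sub)
        return all(h.count(sub) + h.count(rc) <= (1 if h is seq else 0) for h in hay)

    fwd = None
    for start in range(jo_t - min_gap - k, -1, -1):
        cand = seq[start : start + k]
        if unique(cand):
            fwd, f_start = cand, start
            break
    rev = None
    down0 = jo_t + tpl.insertion_length + min_gap
    for start in range(down0, len(seq) - k + 1):
        cand = seq[start : start + k]
        if unique(cand):
            rev, r_end = reverse_complement(cand), start + k
            break
    if fwd is None or rev is None:
        raise ValueError("no unique primer site found; widen flank or lower min_gap")
    return PrimerPair(f"{derivative.name}-junction", fwd, rev, r_end - f_start)


# ---------------------------------------------------------------------------
# Sample-level assays and classification

#: assay name -> structural element that must be present for a positive result
def standard_assays(der_a_name: str = "der(A)", der_b_name: str = "der(B)") -> dict[str, str]:
    return {
        f"{der_a_name}-junction": DER_A,
        f"{der_b_name}-junction": DER_B,
        "refA": NORMAL_A,
        "refB": NORMAL_B,
    }


def assay_sample(content: list[str], assays: dict[str, str]) -> dict[str, bool]:
    """Positive/negative per assay from a sample's structural labels.

    ``content`` lists the structural elements present (quadrivalent labels);
    a junction assay is positive iff its derivative is present, a reference
    assay iff the corresponding normal chromosome is present.
    """
    present = set(content)
    return {name: target in present for name, target in assays.items()}


@dataclass(frozen=True)
class PcrVerdict:
    derA: str  # "positive" | "negative"
    derB: str
    klass: str  # carrier | normal | unbalanced
    conflict: bool = False  # PCR pattern balanced while CNV unbalanced -> review


def pcr_classify(der_a_positive: bool, der_b_positive: bool, cnv_balanced: bool) -> PcrVerdict:
    """Combine the two junction assays with the copy-number verdict.

    A balanced PCR pattern ((+,+) or (-,-)) under an unbalanced CNV screen —
    e.g. a 3:1 segregant carrying both derivatives plus extra material — is
    classified unbalanced on the CNV evidence and flagged for manual review.
    """
    der_a = "positive" if der_a_positive else "negative"
    der_b = "positive" if der_b_positive else "negative"
    conflict = False
    if der_a_positive != der_b_positive:
        klass = "unbalanced"
    elif cnv_balanced:
        klass = "carrier" if der_a_positive else "normal"
    else:
        klass = "unbalanced"
        conflict = True
    return PcrVerdict(der_a, der_b, klass, conflict)
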