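"""Synthetic carrier families and quadrivalent meiotic segregation.

A translocation carrier's two normal homologs (A, B) and two derivatives
(der(A), der(B)) pair as a quadrivalent at meiosis I. The 2:2 segregation
modes distribute them to gametes:

==============  ==============================  =================
mode            gametes (equiprobable)          embryo outcome
==============  ==============================  =================
alternate       {A, B} / {der(A), der(B)}       normal / carrier
adjacent-1      {A, der(B)} / {der(A), B}       unbalanced
adjacent-2      {A, der(A)} / {B, der(B)}       unbalanced
3:1             any 3 of the 4 / the other 1    unbalanced
==============  ==============================  =================

Only alternate segregation yields chromosomally balanced embryos, and it
yields noncarrier and carrier embryos at a 1:1 rate. Clinically, adjacent-1
is the most frequent unbalanced mode, followed by alternate.

Alleles ride on haplotypes: the carrier's homolog involved in the
translocation (transmitted by the carrier's own carrier parent) is the
"translocated" haplotype ``T``; the other is ``N``. Meiotic crossovers
exchange allele content between T and N along each source chromosome
(a homogeneous Poisson process per Mb); structural segment composition is
left intact, so an embryo's karyotype truth stays derivable from its
element labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeBuild
from .translocation import DerivativeChromosome, Segment, TranslocationSpec, make_derivatives

# element labels of the quadrivalent
NORMAL_A, NORMAL_B, DER_A, DER_B = "A", "B", "derA", "derB"
QUADRIVALENT = (NORMAL_A, DER_A, NORMAL_B, DER_B)

#: haplotype indices
HAP_N, HAP_T = 0, 1


@dataclass
class SNPPanel:
    """Bi-allelic SNP positions with population alt-allele frequencies.

    ``positions[chrom]`` is a sorted 1-based int array; ``freqs[chrom]`` the
    matching alt-allele frequency array.
    """

    positions: dict[str, np.ndarray]
    freqs: dict[str, np.ndarray]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def n_sites(self, chrom: str) -> int:
        return len(self.positions[chrom])

    @property
    def total_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())


def make_panel(
    genome: GenomeBuild,
    density_per_mb: float = 30.0,
    min_freq: float = 0.2,
    seed: int = 0,
) -> SNPPanel:
    """Draw a SNP panel: uniform positions, Uniform(min_freq, 1-min_freq)
    alt frequencies. Common alleles keep the informative-site yield high,
    as on a genotyping array."""
    rng = np.random.default_rng(seed)
    positions, freqs = {}, {}
    for chrom, length in genome.chromosomes.items():
        n = max(4, int(round(density_per_mb * length / 1e6)))
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
        positions[chrom] = pos
        freqs[chrom] = rng.uniform(min_freq, 1 - min_freq, size=n)
    return SNPPanel(positions, freqs)


@dataclass
class Individual:
    """One family member: two haplotypes per chromosome plus structural labels.

    ``haplotypes[chrom]`` has shape ``(2, n_sites)`` with 0/1 allele codes;
    row ``HAP_T`` of a carrier is the homolog riding the derivative
    chromosomes. ``karyotype`` is ``"carrier"`` or ``"normal"``.
    """

    identifier: str
    role: str  # carrier | spouse | grandparent-transmitting | grandparent-other
    haplotypes: dict[str, np.ndarray]
    karyotype: str = "normal"

    def genotype(self, chrom: str, site: int) -> tuple[int, int]:
        h = self.haplotypes[chrom]
        return int(h[0, site]), int(h[1, site])

    def genotypes(self, chrom: str) -> np.ndarray:
        """Unphased dosage (0/1/2) per site."""
        return self.haplotypes[chrom].sum(axis=0)


@dataclass
class Family:
    """Carrier couple plus the carrier's parents (the embryos' grandparents)."""

    carrier: Individual
    spouse: Individual
    grandparent_transmitting: Individual
    grandparent_other: Individual
    spec: TranslocationSpec
    der_a: DerivativeChromosome
    der_b: DerivativeChromosome

    @property
    def members(self) -> list[Individual]:
        return [
            self.carrier,
            self.spouse,
            self.grandparent_transmitting,
            self.grandparent_other,
        ]


def _draw_haplotypes(panel: SNPPanel, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        chrom: (rng.random((2, panel.n_sites(chrom))) < panel.freqs[chrom]).astype(np.int8)
        for chrom in panel.chromosomes
    }


def make_family(
    genome: GenomeBuild,
    panel: SNPPanel,
    spec: TranslocationSpec,
    seed: int = 0,
    transmitting_role: str = "grandmother",
) -> Family:
    """Simulate the pedigree: the translocation entered through one of the
    carrier's parents (the transmitting grandparent, itself a carrier), whose
    transmitted haplotype is the carrier's translocated homolog T."""
    rng = np.random.default_rng(seed)
    der_a, der_b = make_derivatives(genome, spec)

    g_trans = Individual(
        transmitting_role, "grandparent-transmitting", _draw_haplotypes(panel, rng), "carrier"
    )
    other_role = "grandfather" if transmitting_role == "grandmother" else "grandmother"
    g_other = Individual(other_role, "grandparent-other", _draw_haplotypes(panel, rng))
    spouse = Individual("spouse", "spouse", _draw_haplotypes(panel, rng))

    # carrier: HAP_T from the transmitting grandparent, HAP_N from the other
    carrier_haps = {}
    for chrom in panel.chromosomes:
        carrier_haps[chrom] = np.stack(
            [g_other.haplotypes[chrom][0].copy(), g_trans.haplotypes[chrom][0].copy()]
        )
    carrier = Individual("carrier", "carrier", carrier_haps, "carrier")
    return Family(carrier, spouse, g_trans, g_other, spec, der_a, der_b)


# ---------------------------------------------------------------------------
# Meiosis


@dataclass(frozen=True)
class SegregationMode:
    """Quadrivalent 2:2/3:1 segregation-mode probabilities (must sum to 1)."""

    alternate: float = 0.35
    adjacent1: float = 0.35
    adjacent2: float = 0.15
    three_to_one: float = 0.15

    def __post_init__(self):
        total = self.alternate + self.adjacent1 + self.adjacent2 + self.three_to_one
        if not np.isclose(total, 1.0):
            raise ValueError(f"segregation-mode probabilities sum to {total}, not 1")

    def draw(self, rng: np.random.Generator) -> str:
        return rng.choice(
            ["alternate", "adjacent1", "adjacent2", "three_to_one"],
            p=[self.alternate, self.adjacent1, self.adjacent2, self.three_to_one],
        )


_MODE_OUTCOMES = {
    "alternate": [(NORMAL_A, NORMAL_B), (DER_A, DER_B)],
    "adjacent1": [(NORMAL_A, DER_B), (DER_A, NORMAL_B)],
    "adjacent2": [(NORMAL_A, DER_A), (NORMAL_B, DER_B)],
}


@dataclass
class GametePiece:
    """Reference interval carried by a gamete element, with its haplotype
    source before crossover adjustment."""

    chrom: str
    start: int
    end: int
    hap: int  # HAP_N or HAP_T
    element: str


@dataclass
class Gamete:
    """One carrier (or spouse) gamete.

    ``elements`` are quadrivalent labels for the translocation chromosomes
    (plus ``"<chrom>"`` labels for the non-translocation chromosomes);
    ``pieces`` give reference coverage with haplotype provenance;
    ``crossovers[chrom]`` are the crossover positions applied to that
    chromosome's allele content.
    """

    elements: list[str]
    pieces: list[GametePiece]
    crossovers: dict[str, list[int]] = field(default_factory=dict)
    mode: str = ""

    def element_pieces(self, element: str) -> list[GametePiece]:
        return [p for p in self.pieces if p.element == element]


def _element_pieces(
    element: str,
    spec: TranslocationSpec,
    genome: GenomeBuild,
    der_a: DerivativeChromosome,
    der_b: DerivativeChromosome,
) -> list[GametePiece]:
    if element == NORMAL_A:
        return [GametePiece(spec.chromA, 1, genome.length(spec.chromA), HAP_N, element)]
    if element == NORMAL_B:
        return [GametePiece(spec.chromB, 1, genome.length(spec.chromB), HAP_N, element)]
    der = der_a if element == DER_A else der_b
    return [GametePiece(s.chrom, s.start, s.end, HAP_T, element) for s in der.segments]


def simulate_meiosis(
    family: Family,
    genome: GenomeBuild,
    panel: SNPPanel,
    rng: np.random.Generator,
    mode: str | None = None,
    mode_probs: SegregationMode | None = None,
    crossover_rate_per_mb: float = 0.0,
) -> Gamete:
    """Draw one carrier gamete.

    ``mode`` forces a segregation mode; otherwise one is drawn from
    ``mode_probs`` (default :class:`SegregationMode`). Crossover positions
    are a Poisson process at ``crossover_rate_per_mb`` per chromosome, and
    exchange allele content between the N and T haplotypes distal to each
    position.
    """
    if mode is None:
        mode = (mode_probs or SegregationMode()).draw(rng)
    if mode in _MODE_OUTCOMES:
        elements = list(_MODE_OUTCOMES[mode][rng.integers(2)])
    elif mode == "three_to_one":
        if rng.integers(2):  # 3-element gamete
            drop = rng.integers(4)
            elements = [e for i, e in enumerate(QUADRIVALENT) if i != drop]
        else:
            elements = [QUADRIVALENT[rng.integers(4)]]
    else:
        raise ValueError(f"unknown segregation mode {mode!r}")

    spec = family.spec
    pieces: list[GametePiece] = []
    for el in elements:
        pieces.extend(_element_pieces(el, spec, genome, family.der_a, family.der_b))
    # non-translocation chromosomes: one random homolog each
    for chrom in panel.chromosomes:
        if chrom in (spec.chromA, spec.chromB):
            continue
        hap = int(rng.integers(2))
        pieces.append(GametePiece(chrom, 1, genome.length(chrom), hap, chrom))
        elements.append(chrom)

    crossovers: dict[str, list[int]] = {}
    if crossover_rate_per_mb > 0:
        for chrom in {p.chrom for p in pieces}:
            lam = crossover_rate_per_mb * genome.length(chrom) / 1e6
            k = rng.poisson(lam)
            if k:
                xs = sorted(int(x) for x in rng.integers(1, genome.length(chrom) + 1, size=k))
                crossovers[chrom] = xs
    return Gamete(elements, pieces, crossovers, mode)


def spouse_gamete(
    family: Family, genome: GenomeBuild, panel: SNPPanel, rng: np.random.Generator
) -> Gamete:
    """One spouse gamete: a random homolog of every chromosome, all normal."""
    pieces = []
    elements = []
    for chrom in panel.chromosomes:
        hap = int(rng.integers(2))
        pieces.append(GametePiece(chrom, 1, genome.length(chrom), hap, chrom))
        elements.append(chrom)
    return Gamete(elements, pieces)


# ---------------------------------------------------------------------------
# Embryos


@dataclass
class Embryo:
    """A conceptus: one carrier gamete + one spouse gamete.

    ``truth`` is derived from the carrier gamete's structural labels:
    {A, B} -> normal; {der(A), der(B)} -> carrier; anything else ->
    unbalanced.
    """

    identifier: str
    carrier_gamete: Gamete
    spouse_gamete: Gamete
    truth: str = field(init=False)

    def __post_init__(self):
        quad = [e for e in self.carrier_gamete.elements if e in QUADRIVALENT]
        content = frozenset(quad)
        if len(quad) == 2:
            if content == {NORMAL_A, NORMAL_B}:
                self.truth = "normal"
            elif content == {DER_A, DER_B}:
                self.truth = "carrier"
            else:
                self.truth = "unbalanced"
        else:
            self.truth = "unbalanced"

    @property
    def structural_content(self) -> list[str]:
        """Quadrivalent elements present (spouse contributes A and B)."""
        quad = [e for e in self.carrier_gamete.elements if e in QUADRIVALENT]
        return sorted(quad) + [NORMAL_A, NORMAL_B]

    @property
    def crossovers(self) -> dict[str, list[int]]:
        return self.carrier_gamete.crossovers


def make_embryo(identifier: str, carrier_gamete: Gamete, spouse_g: Gamete) -> Embryo:
    covered_c = {p.chrom for p in carrier_gamete.pieces}
    covered_s = {p.chrom for p in spouse_g.pieces}
    if covered_s < covered_c:
        raise ValueError("gametes do not cover the same chromosome set")
    return Embryo(identifier, carrier_gamete, spouse_g)


def _crossover_parity(xs: np.ndarray, pos: np.ndarray, anchor: int) -> np.ndarray:
    """Whether an odd number of crossovers separates each position from the
    anchor (the point where a chromatid's allele source is pinned)."""
    if not len(xs):
        return np.zeros(len(pos), dtype=int)
    below = np.searchsorted(xs, pos, side="right")
    below_anchor = int(np.searchsorted(xs, anchor, side="right"))
    return (below - below_anchor) % 2


def _carrier_allele(
    family: Family, panel: SNPPanel, gamete: Gamete, chrom: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (copy count from carrier, alt-allele count from carrier).

    Applies the crossover model: the transmitted haplotype index flips N<->T
    at each crossover position. Allele source is anchored at the breakpoint
    of the translocation chromosomes — a transmitted derivative physically
    carries the junction, so its alleles *at* the junction are always from
    the translocated homolog and switch only where a crossover separates a
    site from the junction. Normal homologs are anchored the same way, so
    structure and allele content stay mutually consistent.
    """
    pos = panel.positions[chrom]
    spec = family.spec
    anchor = spec.posA if chrom == spec.chromA else spec.posB if chrom == spec.chromB else 0
    copies = np.zeros(len(pos), dtype=np.int16)
    alt = np.zeros(len(pos), dtype=np.int16)
    xs = np.asarray(gamete.crossovers.get(chrom, []), dtype=np.int64)
    parity = _crossover_parity(xs, pos, anchor)
    haps = family.carrier.haplotypes[chrom]
    for piece in gamete.pieces:
        if piece.chrom != chrom:
            continue
        mask = (pos >= piece.start) & (pos <= piece.end)
        eff_hap = np.where(parity[mask] == 1, 1 - piece.hap, piece.hap)
        copies[mask] += 1
        alt[mask] += haps[eff_hap, np.flatnonzero(mask)]
    return copies, alt


def _spouse_allele(
    family: Family, panel: SNPPanel, gamete: Gamete, chrom: str
) -> tuple[np.ndarray, np.ndarray]:
    pos = panel.positions[chrom]
    copies = np.zeros(len(pos), dtype=np.int16)
    alt = np.zeros(len(pos), dtype=np.int16)
    haps = family.spouse.haplotypes[chrom]
    for piece in gamete.pieces:
        if piece.chrom != chrom:
            continue
        mask = (pos >= piece.start) & (pos <= piece.end)
        copies[mask] += 1
        alt[mask] += haps[piece.hap, np.flatnonzero(mask)]
    return copies, alt


def embryo_truth_arrays(
    family: Family, panel: SNPPanel, embryo: Embryo, chrom: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """True (copy number, alt-allele count, carrier-transmitted alt count)
    per panel site of ``chrom``."""
    c1, a1 = _carrier_allele(family, panel, embryo.carrier_gamete, chrom)
    c2, a2 = _spouse_allele(family, panel, embryo.spouse_gamete, chrom)
    return c1 + c2, a1 + a2, a1
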