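# Methods

This note documents the models behind `pgtsr`, their assumptions, the
parameters that matter, and what the synthetic data do and do not emulate.

## Coordinates and the breakpoint convention

All internal coordinates are 1-based inclusive; BED and UCSC cytoband files
convert to/from their native 0-based half-open dialect at I/O. A breakpoint
position bounds the retained-proximal side of its chromosome: for a q-arm
breakpoint, bases `[1..pos]` stay with the centromere and `[pos+1..len]`
are exchanged; for a p-arm breakpoint the distal `[1..pos]` fragment is
exchanged. The common two-base junction notation corresponds to
`(pos, pos+1)`. Junction micro-insertions (a signature of non-homologous
end joining) are bounded at 39 bases. Microhomology is modeled as length 0
by default; when a junction is microhomologous the caller reports the full
homology interval rather than picking an edge.

## Derivative chromosomes

`make_derivatives` joins the centric fragment of each chromosome with the
partner's distal fragment. Same-arm exchanges (q/q, p/p) preserve reference
orientation in both segments; a mixed p/q exchange attaches the incoming
fragment break-end first, i.e. inverted in reference orientation, so each
derivative remains monocentric with a telomere at both ends. Derivative
coordinates map bijectively to (chromosome, position, strand) through the
segment list, which drives read simulation, junction templates and
sequence extraction. Synthetic sequence is generated per 64 kb block keyed
by (seed, chromosome, block), so any slice is reproducible in O(slice).

## Segregation and crossover model

The carrier's quadrivalent segregates by one of four modes; the 2:2 modes
yield the canonical element pairs and 3:1 yields a uniformly chosen triple
or singleton. Default mode frequencies are adjacent-1 0.35, alternate 0.35,
adjacent-2 0.15, 3:1 0.15 — the ordering (adjacent-1 most frequent,
alternate next) follows the clinical literature on reciprocal-translocation
quadrivalents; the exact values are free parameters of the generator, not
estimates, since mode frequencies vary per rearrangement.

Crossovers are a homogeneous Poisson process per chromosome (configurable
rate per Mb, default 0 for decision-logic tests; 0.3–1/Mb is a realistic
order for exercising the recombination scan). A crossover exchanges allele
content between the carrier's normal-structure and translocated homologs
distal to its position; the structural segment composition of the gamete is
left intact. Allele source is *anchored at the breakpoint* on the
translocation chromosomes: a transmitted derivative physically carries the
junction, so its alleles at the junction always come from the translocated
homolog and switch only where a crossover separates a site from the
junction. This keeps allele content and structural truth mutually
consistent at the junction — the property the breakpoint-region linkage
assay depends on — at the cost of not modeling structural interchange
(crossovers that convert a derivative into a normal chromatid within the
quadrivalent), which would require tetrad-level simulation.

Embryo truth derives from the carrier gamete's structural labels: {A, B} →
normal, {der(A), der(B)} → carrier, anything else → unbalanced.

## Array observation model

The trophectoderm biopsy is emulated at the genotype level (no raw
intensities): per SNP, a call in {hom-ref, het, hom-alt, no-call}, a copy
signal log2(copy/2), and an alt-allele fraction. Whole-genome-amplification
artifacts: each heterozygous truth call drops one allele with probability
`ado_rate` (survivor equiprobable — so the observed hom-rate among true
hets estimates the ADO rate directly); any call then flips to one of the
other two classes with probability `miscall_rate`; copy signal and allele
fraction carry Gaussian noise `signal_sd` (0.1 is a realistic array scale).
Sites at copy 0 are no-calls with undefined signals. Mosaicism within a
biopsy is not modeled.

## Long reads

Reads are mapped coordinate intervals, not base strings: molecule chosen
proportional to length, start uniform, length geometric with configurable
mean (default 16.7 kb, nanopore scale). A read crossing a junction becomes
a chimeric record with one aligned segment per donor chromosome, split
exactly at the junction; insertion bases consume read offsets without
aligning. `plant_junction_reads` additionally forces junction coverage and
can jitter reported breakend coordinates (default tests use ±200 bp),
emulating alignment imprecision near a breakend. Base-level sequencing
error and basecalling are out of scope.

## Breakpoint calling

Each adjacent pair of read segments on different chromosomes contributes
one junction signal: two breakends with orientations ('R' = retained
sequence extends to lower coordinates). Signals cluster by (chromosome
pair, orientation pair) with single-linkage within `merge_window`
(default 1000 bp, chosen at read-jitter scale) on both sides; the cluster
position is the lower median of member positions (robust to jitter,
deterministic on ties). The two reciprocal junctions of one translocation
have distinct orientation pairs and therefore never merge. Calls with
fewer than `min_support` = 2 distinct spanning reads are flagged
low-support. Database annotation follows the standard population-SV rules:
reciprocal overlap ≥ 0.5 for interval types, breakend distance ≤ 1000 bp
for insertions and translocations. Segment metrics (translocated fragment
size in Mb and percent of chromosome, both half-up rounded to 2 decimals)
use `length − pos` on a q arm and `pos` on a p arm; the arm comes from the
cytoband table or an explicit override.

## Junction PCR

Primer matching is exact string matching on the template plus strand
(thermodynamics out of scope; a mismatch budget is deliberately absent by
default because the assay is validated by sequence, not melting curves).
The product size is the 5'-to-5' distance inclusive; multiple placements
within `max_product` (default 2000 bp, gel-verifiable scale) flag the
result ambiguous. The bundled primer picker chooses unique 20-mers ≥ 50 bp
from the junction as a convenience; user-supplied primers take precedence.
Classification: junction signs (+,+) with a balanced copy-number screen →
carrier, (−,−) balanced → normal, discordant signs → unbalanced; a
balanced sign pattern under an unbalanced screen (e.g. a 3:1 segregant
carrying both derivatives plus extra material) is classified unbalanced on
the CNV evidence and flagged for manual review.

## Copy-number screening

Copy signals are median-smoothed over a centered `window_snps` = 15 window,
classified loss/neutral/gain at −0.30/+0.25 log2 thresholds (chosen so both
noiseless and sd = 0.1 fixtures classify correctly; raw log2 levels are −1,
0, +0.585 for copies 1, 2, 3), merged into runs, and assigned the integer
copy with the nearest log2 anchor. Segment boundaries fall at midpoints
between discordant runs; terminal runs extend to chromosome ends, so a
boundary is localized to about one marker spacing times the window.
Abnormal segments render as `<chrom><bandStart>[<bandEnd>]*<copy>` joined
by "; "; a balanced sample renders the conventional masked notation
`(1–22)*1,(XN)*1` verbatim (including its `*1`-for-disomy quirk, which the
parser treats as an empty abnormal list rather than normalizing).

## Linkage analysis

Informative SNPs require carrier het, spouse hom, reference hom. Phasing
references: (a) the transmitting grandparent — the carrier allele matching
the grandparent's homozygous genotype lies on the grandparent-derived,
i.e. derivative, haplotype; (b) an unbalanced embryo of known structural
content — at sites where the carrier's contribution passes through exactly
one gamete element, the embryo's carrier-inherited allele reveals that
element's haplotype. Both routes agree on shared markers (property-tested).
The carrier-inherited allele in an embryo is always resolvable because the
spouse is homozygous: a het call implies the non-spouse allele, a hom call
implies that allele. Genotypes incompatible with both parents feed a
Mendelian-error counter with a 5 % failure threshold (WGA quality gate).

A breakpoint-region call votes the phased markers within breakpoint ±
`half_width` (default 1 Mb, i.e. a 2 Mb region; sidedness is symmetric by
choice) and requires a strict majority over at least `min_votes` = 3 votes
— regions with as few as 3–4 informative markers do occur, and below 3 a
call is unsafe. Ties and sparse regions return "ambiguous".

The recombination scan maps each phased marker to a derivative/normal
label and accepts a haplotype switch only when sustained over
`persistence` = 3 consecutive markers (a single discordant marker is
indistinguishable from ADO). An event's interval runs from the last marker
of the previous sustained run to the first marker of the next. An event is
flagged "in the breakpoint region" when its interval straddles the
breakpoint itself: that is the case that severs the junction-to-marker
linkage. A crossover that merely reaches into the ± 1 Mb flank leaves the
breakpoint-adjacent markers intact and instead surfaces as mixed votes
(an ambiguous region verdict), so flagging it would double-count; this
choice also matches how reported clinical haplotype blocks that end within
a flank are judged.

Integrated classification: an unbalanced screen dominates; under a
balanced screen, two derivative region calls → carrier, two normal →
normal, anything mixed → ambiguous with a warning (possible in-region
recombination). Concordance between the PCR and linkage verdicts is
reported per cohort.

## Synthetic data: scope of validity

The generator emulates the *logical* structure of a PGT-SR study — meiotic
segregation, marker transmission, WGA noise, junction-spanning evidence —
on four desk-scale chromosomes (5–8.75 Mb, toy cytobands) by default, with
a full-length hg19 build (real chromosome lengths, curated bands for the
four case-study chromosomes) for coordinate-level checks. It does not
emulate: base-level read error, GC/amplification waves in array signal,
mosaicism, structural interchange at meiosis, or population linkage
disequilibrium (panel alleles are drawn independently at Uniform(0.2, 0.8)
frequencies). Passing tests therefore demonstrate the correctness of the
decision logic and calibration of the noise handling, not performance on
real intensity data.

Default problem sizes in the test suite and acceptance script (500-embryo
zero-noise cohort, 20-seed breakpoint recovery, 100-seed region-call
robustness, 5000-gamete segregation ratio) were chosen as the smallest
sizes at which the binomial standard errors make the checks meaningful.

## Bundled case series

`pgtsr.casestudy` is a reconstruction from the printed results of a
clinical PGT-SR case series of two carrier families (twelve biopsied
blastocysts): breakpoints, supporting-read counts, molecular karyotypes,
junction-PCR signs, region verdicts, and recombination blocks. No raw data
were deposited, so the module exists to pin the decision logic against
known verdicts, clearly labeled as a reconstruction. One printed region
verdict ("Negative", defined nowhere among derivative/normal) is treated
as "no informative signal for a region lost from the embryo" and mapped to
ambiguous; the embryo's final class is carried by its unbalanced screen.
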