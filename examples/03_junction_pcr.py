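"""In-silico junction-spanning PCR on derivative and normal templates.

Designs junction primers flanking the der(1) breakpoint, verifies that they
amplify only when the derivative chromosome is present, and classifies
embryos from their two junction assays plus the copy-number verdict.
"""

from pgtsr import (
    TranslocationSpec, design_junction_primers, insilico_pcr, junction_template,
    make_derivatives, pcr_classify, toy_genome,
)
from pgtsr.jpcr import reference_template

genome = toy_genome(seed=0)
spec = TranslocationSpec("chr1", 3_500_000, "chr2", 4_200_000, insertionA="ACGTTGCA")
der_a, der_b = make_derivatives(genome, spec)

primers = design_junction_primers(der_a, genome)
print(f"assay {primers.assay}: F={primers.forward} R={primers.reverse} "
      f"expected {primers.expected_size} bp")

tpl = junction_template(der_a, genome, flank=600)
on_der = insilico_pcr(tpl.sequence, primers)
print(f"on {der_a.name} template: present={on_der.present}, product={on_der.size} bp")

for chrom, pos in (("chr1", spec.posA), ("chr2", spec.posB)):
    ref = reference_template(genome, chrom, pos, flank=1000)
    print(f"on intact {chrom} template: present={insilico_pcr(ref, primers).present}")
# the reverse primer site lies on the partner chromosome, so a product forms
# only across the junction: the assay detects the derivative specifically

print()
for a, b, bal in ((True, True, True), (False, False, True), (True, False, False)):
    v = pcr_classify(a, b, bal)
    print(f"der(A){v.derA[:3]} der(B){v.derB[:3]} cnv_balanced={bal} -> {v.klass}")
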