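"""Classify coding variants and shortlist divergent non-synonymous calls.

Builds a toy gene, classifies SNPs against it (codon comparison), and
filters the non-synonymous calls by the allele-frequency gap between a
domestic and a wild panel — the route by which a single G→D substitution
can be singled out from a sweep region.
"""
from bsasweep import classify_variant, divergent_nonsynonymous
from bsasweep.variant_io import GeneModel, translate_cds

genome = {"chr19": "N" * 10 + "ATGGGTGCTTAA" + "N" * 10}  # protein MGA*
gene = GeneModel("ASNA1-like", "chr19", "+", [(11, 22)])
print("reference protein:", translate_cds(gene, genome))

variants = [
    ("chr19", 15, "G", "A"),   # GGT -> GAT : G2D
    ("chr19", 16, "T", "C"),   # GGT -> GGC : synonymous
    ("chr19", 18, "C", "T"),   # GCT -> GTT : A3V
]
calls = []
for chrom, pos, ref, alt in variants:
    call = classify_variant(chrom, pos, ref, alt, [gene], genome)[0]
    calls.append(call)
    print(f"{chrom}:{pos} {ref}>{alt}  {call.effect:<15} {call.protein_change}")

freqs = {  # (domestic, wild) reference-allele frequencies per site
    ("chr19", 15): (0.02, 0.95),
    ("chr19", 16): (0.01, 0.99),
    ("chr19", 18): (0.55, 0.45),
}
short = divergent_nonsynonymous(calls, freqs, freq_gap=0.8)
print("divergent non-synonymous:",
      [(c.pos, c.protein_change) for c in short])
# Only the G2D call is both amino-acid changing and near-fixed
# differently in the two panels (gap >= 0.8).
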