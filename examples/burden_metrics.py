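"""Somatic filtering and the TMB / TNB / MATH burden metrics on a toy lesion.

Five hand-written variants exercise all four filter rules (non-silent
consequence, VAF > 0.03, depth >= 50x, population frequency < 0.01);
the burden metrics are then computed over the survivors.
"""

import timepair as tp

variants = [
    tp.VariantRecord("chr17", 7_578_406, "C", "T", "TP53", "missense", 0.20, 100, 0.0),
    tp.VariantRecord("chr12", 25_398_284, "C", "A", "KRAS", "silent", 0.40, 200, 0.0),
    tp.VariantRecord("chr7", 55_242_464, "A", "T", "EGFR", "missense", 0.02, 300, 0.0),
    tp.VariantRecord("chr3", 178_936_091, "G", "A", "PIK3CA", "frameshift", 0.15, 60, 0.02),
    tp.VariantRecord("chr9", 21_971_120, "C", "G", "CDKN2A", "splice_site", 0.10, 50, 0.005),
]

kept = tp.filter_somatic_variants(variants)
print(f"{len(kept)} of {len(variants)} variants pass the somatic filter:")
for v in kept:
    print(f"  {v.gene} {v.consequence_class.value} VAF={v.vaf} depth={v.depth}")

exonic_bases = 5e7  # V6-class whole-exome capture
tmb = tp.compute_tmb(len(kept), exonic_bases)
tnb = tp.compute_tnb(3, exonic_bases / 1e6)
math_score = tp.compute_math([v.vaf for v in kept])
print(f"TMB  = {tmb:.4f} mutations/Mb (count / captured Mb)")
print(f"TNB  = {tnb:.4f} neoantigens/Mb (neoantigen count is an upstream input)")
print(f"MATH = {math_score:.3f} (100 x scaled MAD of VAFs / median VAF; "
      "higher = more subclonal heterogeneity)")

call = tp.classify_cnv(5.1, gene="MYC")
print(f"CNV: {call.gene} copy {call.copy_number} -> {call.state.value} "
      "(gain at copy >= 4, loss at copy <= 1.2)")
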