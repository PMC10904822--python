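"""Hypergeometric over-representation of a differential gene list.

Runs the paired DEG screen on a simulated cohort, then asks whether the
retained genes are enriched in toy gene-set collections (any GMT file —
e.g. a pathway-database export — can be supplied instead).
"""

import timepair as tp

bundle = tp.simulate_cohort(tp.CohortConfig(master_seed=42))
log_expr = tp.log2_normalize(tp.counts_to_tpm(bundle.counts, bundle.gene_lengths))
degs = tp.paired_deg_filter(log_expr, bundle.design)
query = {r.gene for r in degs}
print(f"{len(query)} genes pass |log2FC| > 1 and p < 0.05 (SQCC vs ADC, paired)")

universe = set(log_expr.genes)
planted = {g for g, v in bundle.truth.de_status.items() if v}
unrelated = sorted(g for g in universe if g.startswith("GENE") and g not in planted)[:100]
collection = tp.GeneSetCollection(
    sets={
        "planted_de_genes": sorted(planted),
        "marker_panel_genes": bundle.config.marker_panel.all_genes,
        "unrelated_background": unrelated,
    },
    universe=universe,
)
table = tp.hypergeometric_ora(query, collection)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("-> the planted and infiltration-shifted sets top the list; an "
      "unrelated set shows overlap near its expectation with p ~ 1.")
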