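"""Generate a synthetic paired ADC/SQCC cohort and inspect its ground truth.

Builds the default five-patient cohort (one adenocarcinoma and one
squamous lesion each), writes the bundle to disk, and prints the planted
truth the downstream stages are later asked to recover.
"""

import tempfile

import timepair as tp

config = tp.CohortConfig(master_seed=42)
bundle = tp.simulate_cohort(config)

print(f"lesions: {bundle.design.samples}")
print(f"expression matrix: {bundle.counts.values.shape[0]} genes x "
      f"{bundle.counts.values.shape[1]} samples ({bundle.counts.unit.value})")
print(f"variants per lesion: { {k: len(v) for k, v in bundle.variants.items()} }")

loh_lesions = sorted(l for l, loci in bundle.truth.loh_status.items() if any(loci.values()))
print(f"planted HLA-LOH lesions ({len(loh_lesions)}/10): {loh_lesions}")

lat = bundle.truth.latent_infiltration
gaps = [lat[a] - lat[s] for a, s in zip(bundle.design.adc_sample, bundle.design.sqcc_sample)]
print("per-patient ADC - SQCC latent infiltration gaps:",
      [round(g, 2) for g in gaps])
print("-> positive gaps are the planted 'immune-hot ADC' phenotype the "
      "TIL-scoring stage should detect.")

with tempfile.TemporaryDirectory() as tmp:
    paths = tp.write_bundle(bundle, tmp)
    print(f"bundle written as {len(paths)} plain-text files (TSV/VCF/GMT/JSON)")
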