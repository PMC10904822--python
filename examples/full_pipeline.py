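"""The file-driven end-to-end run: simulate, persist, analyze, report.

Equivalent to `timepair simulate ...` followed by `timepair run ...` on
the shell; every stage output lands as a TSV/JSON file next to a
provenance block with the config hash.
"""

import tempfile
from pathlib import Path

import timepair as tp
from timepair.pipeline import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    bundle_dir = Path(tmp) / "bundle"
    out_dir = Path(tmp) / "report"
    tp.write_bundle(tp.simulate_cohort(tp.CohortConfig(master_seed=42)), bundle_dir)

    report = run_pipeline(RunConfig(bundle_dir=str(bundle_dir), output_dir=str(out_dir)))

    print("per-lesion burden (first rows):")
    print(report.burden.head(3).to_string(float_format=lambda v: f"{v:.3g}"))
    print(f"\nHLA-LOH: {report.loh_summary['lesion_pct']:.0f}% of lesions, "
          f"{report.loh_summary['patient_pct']:.0f}% of patients")
    til = report.comparisons.set_index("metric").loc["til_score"]
    print(f"TIL score: {til['direction']} (paired t, p = {til['p']:.4f})")
    print(f"\nstage outputs written: {sorted(p.name for p in out_dir.iterdir())}")
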