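# timepair

Paired-lesion multi-omic analysis for **multiple primary lung cancer with
concurrent adenocarcinoma (ADC) and squamous cell carcinoma (SQCC)** — the
setting where one patient carries two independent tumors of different
histology, and every comparison can be made within-patient.

`timepair` is a Python library (plus a thin `timepair` CLI) for
computational oncologists and bioinformaticians working with small paired
tumor cohorts. It implements, as tested reusable stages:

- **Somatic variant metrics** — the four-rule somatic filter (non-silent
  consequence; VAF > 0.03; depth ≥ 50×; population frequency < 0.01) and
  the burden/heterogeneity statistics computed over the survivors:

  - TMB = mutations × 10⁶ / exonic bases (mutations/Mb)
  - TNB = neoantigens / Mb (neoantigen counts are an upstream input)
  - MATH = 100 × MAD(VAF) / median(VAF), scaled MAD by default
  - CNV gain/loss classification (copy ≥ 4 gain, ≤ 1.2 loss)

- **HLA class-I loss of heterozygosity** — per-lesion calling from
  per-allele unique read counts and copy estimates: LOH iff minor-allele
  copy < 0.5 **and** exact-binomial allelic imbalance p < 0.01; plus
  4-digit genotype handling and supertype assignment (bundled
  allele → supertype table, e.g. B\*15:01 → B62).

- **Expression normalization and a paired DEG screen** — counts → TPM →
  log2(TPM+1); per gene, the paired SQCC−ADC log2 fold change and a paired
  t-test, retaining |log2FC| > 1 and p < 0.05.

- **TIME scoring** (the core) — co-expression scoring of the tumor immune
  microenvironment: 14 immune-population *cell scores* (mean marker-gene
  log2 expression), a total *TIL score* averaging the populations whose
  correlation with the pan-leukocyte anchor PTPRC (CD45) exceeds 0.6,
  per-population *enrichment residuals* from OLS on the TIL score, and 9
  immune-characteristic *signature scores* (checkpoints, chemokines, MHC
  machinery, …). Panels/signatures are GMT files; defaults are bundled.

- **Paired comparison** — paired t-test and an *exact* Wilcoxon
  signed-rank test (full sign-assignment null up to n = 25, midranks for
  ties). With five pairs the signed-rank two-sided p is floored at
  2/2⁵ = 0.0625, which is why the default policy sends burden metrics to
  the signed-rank test and continuous scores/densities to the paired t.

- **Hypergeometric ORA** — over-representation of a gene list against any
  GMT collection with an explicit universe.

- **A synthetic paired-cohort generator** — negative-binomial expression
  with a latent infiltration factor elevated in ADC, Beta-distributed
  VAFs, planted HLA-LOH, and lognormal mIHC densities, with full ground
  truth, so every stage is testable end-to-end without restricted patient
  data.

## Worked example

```python
import timepair as tp

bundle = tp.simulate_cohort(tp.CohortConfig(master_seed=42))  # 5 patients x 2 lesions
report = tp.analyze_bundle(bundle)

print(report.loh_summary["lesion_pct"])        # 60.0  -> % lesions with HLA-LOH
row = report.comparisons.set_index("metric").loc["til_score"]
print(row["direction"], round(row["p"], 4))    # higher_in_adc 0.0003
```

The seeded default cohort plants a 1.5 log2-unit ADC excess on the latent
infiltration factor and LOH in 6/10 lesions; the pipeline recovers both —
the TIL score is higher in ADC by a paired t-test (p ≈ 0.0003), and 60%
of lesions are called LOH-positive. The `examples/` directory holds one
short narrative script per capability (`python examples/til_scoring.py`,
…), each printing the numbers it computes and what they mean.

The same flow is available from a shell:

```bash
timepair simulate --seed 42 --out bundle/
timepair run --bundle-dir bundle/ --out-dir report/
```

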