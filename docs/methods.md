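# Methods

This note documents the statistical model behind each stage, the
defaults that matter, what the synthetic cohort generator does and does
not emulate, and the numerical choices at the edges.

## Somatic variant metrics

A variant survives the somatic filter iff all four rules hold: its
consequence class is non-silent (missense, nonsense, frameshift,
splice-site), VAF > 0.03 (strict), depth ≥ 50× (inclusive), and maximum
population-database frequency < 0.01 (strict). Inclusivity follows the
usual reading of the printed operators; both boundaries of the CNV rule
(gain at copy ≥ 4, loss at copy ≤ 1.2) are inclusive. A record with a
missing annotation (NaN) is a validation error naming the record and
field — missingness must never silently pass or fail a filter.

- **TMB** = n × 10⁶ / exonic bases. The captured exonic base count is a
  *required* parameter with no hidden default; examples use 5 × 10⁷ bp,
  the scale of a V6-class whole-exome capture. TMB counts post-filter
  variants by default (`count_filtered=False` counts the raw input);
  which convention a given study used is often unstated, so both are
  exposed.
- **TNB** = neoantigen count / region Mb. Neoantigen prediction is an
  upstream epitope pipeline; its count is an input here.
- **MATH** = 100 × scale × MAD(VAF) / median(VAF). The MATH literature
  conventionally uses the scaled MAD (×1.4826, the Gaussian consistency
  constant), but the formula is sometimes quoted without it; the default
  is 1.4826 with `scale_constant=1.0` reproducing the raw-MAD reading.
  MATH is scale-invariant in the VAFs and zero for a single variant. A
  lesion with no surviving variants reports MATH 0 rather than erroring.

## HLA-LOH calling

The caller implements a two-condition decision rule on per-allele
evidence (unique read count, counting each sequencing read once, and an
allele-specific copy-number estimate produced upstream):

LOH ⇔ min(copy₁, copy₂) < 0.5 **and** exact two-sided binomial
p(reads₁ | n = reads₁+reads₂, p₀ = 0.5) < α, default α = 0.01.

This is deliberately a decision rule, not a re-implementation of a full
allele-specific copy-number pipeline (binning, B-allele frequencies,
purity/ploidy are out of scope). The copy condition is applied to the
minor allele. The lost allele is the lower-copy allele, ties broken by
lower read count then lexicographic name, making calls deterministic.
Homozygous loci yield a flagged not-applicable call — LOH is undefined
there — rather than an exception. A lesion is LOH-positive if any locus
is called; patients if any lesion is.

Calibration at the defaults (measured by `scripts/acceptance.py`): the
false-positive rate on balanced loci (copies ≈ 1, reads 50:50, ~300
reads) is ≤ 0.01, and sensitivity at minor copy 0.2 with ≥ 200 unique
reads is ≥ 0.95 over 1000 simulated loci each.

Supertype assignment uses a bundled ~60-allele A/B-locus table in the
classical A01/A02/A03/A24/B07/B08/B27/B44/B58/B62 scheme; alleles absent
from the table (including all C alleles) map to "unclassified" and never
error. Users can substitute any allele → supertype mapping.

## Expression normalization and the paired DEG screen

TPM per column: rateᵍ = countᵍ/lengthᵍ, tpmᵍ = rateᵍ/Σrate × 10⁶, so
each column sums to one million (conserved to ≈1e-9 in practice). An
all-zero column has undefined TPM and errors. The log2 transform uses
pseudocount 1 by default (configurable, recorded in metadata).

The DEG screen is a paired-design threshold rule on log2(TPM+1): per
gene, log2FC = mean over patients of (SQCC − ADC), p from a paired
t-test on the within-patient differences, retaining |log2FC| > 1 AND
p < 0.05, both strict. The orientation (SQCC relative to ADC) and the
pseudocount travel in the output metadata. Raw p drives retention —
matching how such screens are usually reported at n = 5 — with a
Benjamini–Hochberg column emitted alongside. A count-model Wald test
(e.g. a paired negative-binomial regression) would be the heavier
alternative; the thresholding rule itself, not a particular test
statistic, is the contract this stage fixes, and the stand-in is labeled
in the output. Genes with zero-variance differences have undefined p and
are never retained.

## TIME scoring

All scoring operates on log2(TPM+1).

- **Cell scores**: mean log2 expression of each population's marker
  genes; 14 bundled populations (B cells, CD45, CD8 T, cytotoxic,
  dendritic, exhausted CD8, macrophages, mast, neutrophils, NK CD56dim,
  NK, T cells, Th1, Treg) with 3–8 markers each, user-replaceable via
  GMT. Missing genes are dropped with a warning and the score uses the
  resolvable subset (FFPE panels routinely miss genes); `strict=True`
  errors instead; a population with no resolvable gene always errors.
- **TIL score**: Pearson correlation (Spearman by flag) of each
  population's score vector with the anchor gene's expression across
  samples; populations with r strictly > 0.6 are averaged per sample.
  The anchor is PTPRC (CD45), the pan-leukocyte marker; it may not be a
  member of any population list, so the CD45 population carries
  pan-leukocyte companion markers (PTPRCAP, CD52, LAPTM5, CD48) instead.
  Zero-variance vectors make the correlation undefined; the population
  is excluded with a machine-readable warning. An empty gate is an
  explicit error — the method makes no call on such a cohort.
- **Enrichment scores**: per-population OLS of cell score on TIL score
  (intercept included) across samples; the residuals measure abundance
  or depletion relative to total infiltration. Residuals sum to zero and
  are orthogonal to the TIL vector by construction; a constant TIL score
  is a degenerate regression and errors.
- **Signature scores**: nine immune-characteristic gene sets (adhesion
  molecules, chemokines, cytolytic activity, immunocostimulators,
  immunoinhibitors, MHC-I, MHC-II, non-classical MHC, IFNγ response).
  "Mean" aggregation is the default — dimensionally consistent with cell
  scores — with a "sum" mode flag; the mode is recorded in the result.
  Exhausted-CD8 auxiliary markers (PD-1, PD-L1, CD244) are handled as
  single-gene signatures fed to the comparison stage, not as a separate
  operation.

Shifting all log-expression values by a constant shifts every score by
that constant and leaves correlations and residuals unchanged; raising
the gate threshold can only shrink the included set.

## Paired comparison

Convention: x = ADC, y = SQCC, aligned by patient; positive differences
report `higher_in_adc`. The paired t-test is two-sided; zero-variance
differences give a flagged degenerate result (p undefined), not an
exception. The Wilcoxon signed-rank test drops zero differences before
ranking (Pratt's method by flag), uses midranks for ties, and computes
the exact two-sided p for up to 25 non-zero pairs by convolving the
doubled-rank null — arithmetically identical to enumerating all 2ⁿ sign
assignments — with p = 2·min(lower, upper) tails capped at 1; beyond 25
pairs a tie-corrected normal approximation is used. At n = 5 the exact
two-sided p is floored at 0.0625, so any sub-0.05 result on five pairs
must come from the t-test; the default policy therefore routes burden
metrics (tmb/tnb/math) to the signed-rank test and all continuous
scores and densities to the paired t. "Paired Wilcoxon rank-sum" in
common usage is read as the signed-rank test — "paired" governs. No
cross-metric multiplicity correction is applied by default (per-metric
raw p is the convention in small paired designs); a BH flag exists.

## Over-representation analysis

Upper-tail hypergeometric per set: with m set genes in the universe and
k overlapping the query, p = P(X ≥ k) drawing |query| from the universe.
k = 0 reports p = 1; results sort by ascending p with BH alongside. The
universe is a required explicit input because the choice (all annotated
vs expressed genes) changes every p value, and no pathway content is
bundled — any GMT export works.

## Synthetic cohort generator

The generator emulates the data *shape* of a five-patient concurrent
ADC/SQCC cohort (ten lesions, WES + bulk RNA-seq + mIHC arms):

- **Expression**: negative-binomial counts (dispersion 0.3, the bulk
  RNA-seq convention) with expected counts ∝ expression × gene length,
  scaled to ~3 × 10⁶ assigned reads; gene lengths uniform 500–10,000 bp
  so TPM's length correction is exercised. Marker genes load on a latent
  infiltration factor z (loadings U(0.8, 1.2); the anchor PTPRC loads at
  1.0; signature genes at U(0.5, 1.0)). The factor decomposes as
  z = u_patient + e_lesion + effect·1[ADC], with u ~ N(0, 1.0) and
  e ~ N(0, 0.3). The dominance of the patient component is deliberate:
  cross-sample shared variance is what makes the r > 0.6 anchor gate
  satisfiable, while the paired design cancels u, leaving within-pair
  noise small enough for a five-pair t-test to detect the default
  1.5-log2 ADC effect with high power. Both facts follow from the
  variance algebra and are verified by the replicated experiments.
  Planted histology-DE genes (default 100 background genes, ±2.0 log2,
  alternating sign) give the DEG screen a known answer.
- **Variants**: per-lesion counts Poisson (means 100 ADC / 120 SQCC —
  similar by design, as burden differences are not a feature of this
  phenotype), VAF ~ Beta(2, 8) (mean 0.2, right-skewed, as in impure
  FFPE tumor tissue), overdispersed depths around 150× so a tail fails
  the 50× rule, and 10% of sites carrying nonzero population frequency
  so the rare-variant rule bites. Neoantigen counts are a 12% binomial
  thinning of each lesion's mutations.
- **HLA**: heterozygous genotypes drawn from a small allele pool; LOH
  planted in round(fraction × 10) lesions (default 0.6 → 6/10) at one
  random locus each, with minor copy U(0.1, 0.4) and read counts skewed
  by the copy ratio; non-LOH loci have copies ≈ 1 and balanced counts.
- **Densities**: lognormal (σ_log 0.4) per marker × region, with the
  ADC excess (default 0.7 log units) applied to immune markers (CD8,
  CD68, PD-1, PD-L1) but not the epithelial marker PANCK.

One master seed drives fixed per-modality substreams, so any modality
regenerates independently and bundles are bit-reproducible. Ground truth
(latent values, LOH loci, planted DE genes, density means) is carried in
a `TruthRecord`.

**What passing tests show, and what they do not.** The generator
produces the right formats, realistic marginal scales, and a planted,
recoverable effect structure. It does not emulate isoform structure,
GC/mappability bias, subclonal copy-number architecture, purity
gradients, batch effects, or spatial heterogeneity — so end-to-end
recovery demonstrates the pipeline's statistical machinery is correct
and calibrated, not that real FFPE cohorts of this size will yield the
same power.

## Replicated-experiment sizes and numerical choices

The self-checks run 100 effect cohorts and 200 matched null cohorts at
the full default size (5 patients, 5000 genes), 1000 simulated loci per
LOH operating characteristic, and ≥1000 random instances per
formula-vs-brute-force oracle — sizes chosen to give stable rates while
keeping a full run in the minutes range on one CPU. In roughly 2–3% of
five-patient cohorts the patient latents cluster tightly enough that no
population clears the r > 0.6 gate; the scoring stage then raises an
explicit error, and replicated experiments count such cohorts as
non-detections (the method makes no call). Exact binomial and
hypergeometric tails come from scipy; the signed-rank null is an integer
dynamic program over doubled midranks; OLS uses `numpy.linalg.lstsq`.
Round-trips through the I/O layer are exact for integers and strings
and ≤ 1e-9 for reals (VCF float INFO fields are re-read from the raw
text because htslib holds them as float32).

## Known limitations

- The bundled marker panel and signature sets are reasonable defaults
  assembled from the co-expression scoring literature, not a validated
  clinical panel; real analyses should supply their own GMTs.
- The DEG stage's paired t on log2(TPM+1) is a thresholding stand-in,
  not a count-model test; very low-count genes are better served by a
  negative-binomial framework.
- The LOH caller consumes upstream copy/read evidence; it cannot rescue
  biased typing or alignment.
- With five pairs, all tests are power-limited and the signed-rank p is
  floored at 0.0625; conclusions at this n are descriptive, not
  confirmatory.
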