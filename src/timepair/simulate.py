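"""Synthetic paired ADC/SQCC cohort generator with known ground truth.

Emulates the data shape of a five-patient concurrent-histology cohort
in which each patient contributes one adenocarcinoma (``P*_AD``) and one
squamous (``P*_SQ``) lesion, with four modalities:

* a bulk RNA-seq count matrix (negative-binomial counts; immune marker
  genes load on a latent infiltration factor that is elevated in ADC);
* per-lesion somatic variant tables (Poisson mutation counts with
  Beta-distributed VAFs);
* per-allele HLA class-I evidence with LOH planted in a configurable
  fraction of lesions;
* lognormal mIHC cell densities with a planted ADC excess.

The latent infiltration factor decomposes into a patient-level component
(shared by a patient's two lesions) and a lesion-level component, plus
the fixed ADC effect. Between-patient variation dominates by default,
which makes the anchor-correlation gate of the scoring stage satisfiable
while keeping within-pair noise small enough for the paired comparison
to detect the planted effect. One master seed drives fixed per-modality
substreams, so each modality is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .design import PairedDesign
from .errors import ConfigurationError
from .matrix import ExpressionMatrix, Unit
from .scoring import MarkerPanel, SignatureSet
from .variants import Consequence, VariantRecord

_SUBSTREAM = {"genes": 0, "expression": 1, "variants": 2, "hla": 3, "densities": 4}

_CONSEQUENCES = [
    (Consequence.MISSENSE, 0.70),
    (Consequence.NONSENSE, 0.05),
    (Consequence.FRAMESHIFT, 0.06),
    (Consequence.SPLICE_SITE, 0.05),
    (Consequence.SILENT, 0.11),
    (Consequence.OTHER, 0.03),
]

_HLA_POOL = {
    "A": ["A*01:01", "A*02:01", "A*02:06", "A*03:01", "A*11:01", "A*24:02", "A*31:01", "A*33:03"],
    "B": ["B*07:02", "B*15:01", "B*35:01", "B*40:01", "B*44:03", "B*46:01", "B*51:01", "B*58:01"],
    "C": ["C*01:02", "C*03:04", "C*04:01", "C*07:02", "C*08:01", "C*14:02"],
}

_DENSITY_MARKERS = ["CD8", "CD68", "PD-1", "PD-L1", "PANCK"]
_DENSITY_BASELINE_LOG = {"CD8": 4.5, "CD68": 4.2, "PD-1": 3.0, "PD-L1": 3.2, "PANCK": 6.5}
_IMMUNE_DENSITY_MARKERS = {"CD8", "CD68", "PD-1", "PD-L1"}


@dataclass
class CohortConfig:
    """Study conditions of the simulated paired cohort.

    Defaults emulate a five-patient, ten-lesion concurrent ADC/SQCC
    cohort: a 1.5 log2-unit ADC excess on the latent infiltration
    factor, ~100-150 somatic mutations per lesion with Beta(2, 8) VAFs,
    HLA-LOH in 60% of lesions, and a 0.7 log-unit ADC excess in immune
    mIHC densities.
    """

    n_patients: int = 5
    n_genes: int = 5000
    marker_panel: MarkerPanel = field(default_factory=MarkerPanel.default)
    signature_sets: SignatureSet = field(default_factory=SignatureSet.default)
    infiltration_effect: float = 1.5
    patient_sd: float = 1.0
    lesion_sd: float = 0.3
    dispersion: float = 0.3
    mean_mutations_adc: float = 100.0
    mean_mutations_sqcc: float = 120.0
    vaf_alpha: float = 2.0
    vaf_beta: float = 8.0
    loh_lesion_fraction: float = 0.6
    density_effect: float = 0.7
    n_planted_de: int = 100
    de_effect: float = 2.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_genes"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("mean_mutations_adc", "mean_mutations_sqcc", "vaf_alpha", "vaf_beta"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("patient_sd", "lesion_sd", "dispersion"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.loh_lesion_fraction <= 1.0:
            raise ConfigurationError(
                f"loh_lesion_fraction must lie in [0, 1], got {self.loh_lesion_fraction}"
            )
        if self.n_planted_de < 0:
            raise ConfigurationError(f"n_planted_de must be >= 0, got {self.n_planted_de}")


@dataclass
class TruthRecord:
    """Ground truth planted by the generator, one entry per simulated unit."""

    latent_infiltration: dict[str, float]
    loh_status: dict[str, dict[str, bool]]
    de_status: dict[str, bool]
    density_means: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class CohortBundle:
    """Everything one simulated cohort produces, ready for the pipeline."""

    counts: ExpressionMatrix
    gene_lengths: dict[str, float]
    variants: dict[str, list[VariantRecord]]
    neoantigen_counts: dict[str, int]
    hla_genotypes: pd.DataFrame
    hla_evidence: pd.DataFrame
    densities: pd.DataFrame
    design: PairedDesign
    truth: TruthRecord
    config: CohortConfig


def _rng(config: CohortConfig, modality: str) -> np.random.Generator:
    return np.random.default_rng([int(config.master_seed), _SUBSTREAM[modality]])


def _gene_universe(config: CohortConfig) -> list[str]:
    """Background genes plus every panel/signature gene and the anchor."""
    special: dict[str, None] = {}
    special.setdefault(config.marker_panel.anchor_gene)
    for g in config.marker_panel.all_genes:
        special.setdefault(g)
    for g in config.signature_sets.all_genes:
        special.setdefault(g)
    n_background = max(config.n_genes - len(special), 0)
    background = [f"GENE{i + 1:05d}" for i in range(n_background)]
    return list(special) + background


def simulate_expression(
    config: CohortConfig, design: PairedDesign
) -> tuple[ExpressionMatrix, dict[str, float], dict[str, float], dict[str, bool]]:
    """NB count matrix, gene lengths, latent factor values, and planted-DE truth."""
    genes = _gene_universe(config)
    gene_rng = _rng(config, "genes")
    lengths = dict(zip(genes, gene_rng.uniform(500, 10_000, size=len(genes))))
    baseline_log2 = gene_rng.normal(4.0, 1.5, size=len(genes))

    anchor = config.marker_panel.anchor_gene
    loadings = np.zeros(len(genes))
    index_of = {g: i for i, g in enumerate(genes)}
    loadings[index_of[anchor]] = 1.0
    for pop_genes in config.marker_panel.populations.values():
        for g in pop_genes:
            loadings[index_of[g]] = gene_rng.uniform(0.8, 1.2)
    for g in config.signature_sets.all_genes:
        if loadings[index_of[g]] == 0.0:
            loadings[index_of[g]] = gene_rng.uniform(0.5, 1.0)

    # planted histology DE on background genes only (marker genes already
    # shift with the infiltration effect); positive shift = up in SQCC
    background = [g for g in genes if loadings[index_of[g]] == 0.0]
    n_de = min(config.n_planted_de, len(background))
    de_genes = list(gene_rng.choice(background, size=n_de, replace=False)) if n_de else []
    de_shift = np.zeros(len(genes))
    for k, g in enumerate(de_genes):
        de_shift[index_of[g]] = config.de_effect if k % 2 == 0 else -config.de_effect
    de_status = {g: bool(de_shift[index_of[g]] != 0.0) for g in genes}

    expr_rng = _rng(config, "expression")
    latent: dict[str, float] = {}
    for patient, adc, sqcc in zip(design.patients, design.adc_sample, design.sqcc_sample):
        u = expr_rng.normal(0.0, config.patient_sd)
        latent[adc] = u + expr_rng.normal(0.0, config.lesion_sd) + config.infiltration_effect
        latent[sqcc] = u + expr_rng.normal(0.0, config.lesion_sd)

    length_arr = np.array([lengths[g] for g in genes])
    columns = {}
    for sample in design.samples:
        is_sqcc = design.histology_of(sample) == "SQCC"
        log2_mean = baseline_log2 + loadings * latent[sample]
        if is_sqcc:
            log2_mean = log2_mean + de_shift
        # expected counts proportional to expression x length, scaled to
        # a realistic bulk library (~3e6 assigned reads)
        rel = np.power(2.0, log2_mean) * length_arr
        mean_counts = rel / rel.sum() * 3e6
        if config.dispersion > 0:
            n_param = 1.0 / config.dispersion
            p_param = n_param / (n_param + mean_counts)
            columns[sample] = expr_rng.negative_binomial(n_param, p_param)
        else:
            columns[sample] = expr_rng.poisson(mean_counts)
    counts = pd.DataFrame(columns, index=genes)
    matrix = ExpressionMatrix(values=counts, unit=Unit.COUNTS)
    return matrix, lengths, latent, de_status


def simulate_variants(
    config: CohortConfig, design: PairedDesign
) -> tuple[dict[str, list[VariantRecord]], dict[str, int]]:
    """Per-lesion somatic variant tables with Beta-distributed VAFs.

    Also emits a per-lesion neoantigen count (a thinned fraction of the
    lesion's mutations) standing in for the upstream epitope-prediction
    output the burden stage treats as an input.
    """
    rng = _rng(config, "variants")
    genes = _gene_universe(config)
    classes, weights = zip(*_CONSEQUENCES)
    bases = np.array(list("ACGT"))
    tables: dict[str, list[VariantRecord]] = {}
    for sample in design.samples:
        mean = (
            config.mean_mutations_adc
            if design.histology_of(sample) == "ADC"
            else config.mean_mutations_sqcc
        )
        n = int(rng.poisson(mean))
        records = []
        for _ in range(n):
            ref, alt = rng.choice(bases, size=2, replace=False)
            vaf = float(np.clip(rng.beta(config.vaf_alpha, config.vaf_beta), 0.005, 0.995))
            # overdispersed depth so a tail of sites fails the 50x rule
            depth = int(rng.negative_binomial(5.0, 5.0 / (5.0 + 150.0)))
            popfreq = float(rng.beta(0.5, 25.0)) if rng.random() < 0.10 else 0.0
            records.append(
                VariantRecord(
                    chromosome=f"chr{rng.integers(1, 23)}",
                    position=int(rng.integers(1, 100_000_000)),
                    ref=str(ref),
                    alt=str(alt),
                    gene=str(rng.choice(genes)),
                    consequence_class=classes[int(rng.choice(len(classes), p=weights))],
                    vaf=vaf,
                    depth=depth,
                    population_frequency=min(popfreq, 1.0),
                )
            )
        tables[sample] = records
    neoantigens = {s: int(rng.binomial(len(tables[s]), 0.12)) for s in design.samples}
    return tables, neoantigens


def simulate_hla(
    config: CohortConfig, design: PairedDesign
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict[str, bool]]]:
    """Heterozygous genotypes, per-allele lesion evidence, and planted LOH truth."""
    rng = _rng(config, "hla")
    genotype_rows = []
    patient_alleles: dict[str, dict[str, tuple[str, str]]] = {}
    for patient in design.patients:
        patient_alleles[patient] = {}
        for locus, pool in _HLA_POOL.items():
            a1, a2 = rng.choice(pool, size=2, replace=False)
            patient_alleles[patient][locus] = (str(a1), str(a2))
            genotype_rows.append(
                {"patient": patient, "locus": locus, "allele1": str(a1), "allele2": str(a2)}
            )

    lesions = design.samples
    n_loh = int(round(config.loh_lesion_fraction * len(lesions)))
    loh_lesions = set(rng.choice(lesions, size=n_loh, replace=False)) if n_loh else set()
    loci = list(_HLA_POOL)

    evidence_rows = []
    truth: dict[str, dict[str, bool]] = {}
    for lesion in lesions:
        patient = design.patient_of(lesion)
        lost_locus = str(rng.choice(loci)) if lesion in loh_lesions else None
        truth[lesion] = {locus: locus == lost_locus for locus in loci}
        for locus in loci:
            a1, a2 = patient_alleles[patient][locus]
            total_reads = int(rng.poisson(300))
            if locus == lost_locus:
                minor_copy = float(rng.uniform(0.1, 0.4))
                major_copy = float(max(rng.normal(1.1, 0.1), 0.8))
                p_minor = minor_copy / (minor_copy + major_copy)
            else:
                minor_copy = float(max(rng.normal(1.0, 0.05), 0.55))
                major_copy = float(max(rng.normal(1.0, 0.05), 0.55))
                p_minor = 0.5
            reads1 = int(rng.binomial(total_reads, p_minor))
            for allele, copy, reads in (
                (a1, minor_copy, reads1),
                (a2, major_copy, total_reads - reads1),
            ):
                evidence_rows.append(
                    {
                        "lesion": lesion,
                        "locus": locus,
                        "allele": allele,
                        "unique_reads": reads,
                        "copy_number": round(copy, 6),
                    }
                )
    return pd.DataFrame(genotype_rows), pd.DataFrame(evidence_rows), truth


def simulate_densities(
    config: CohortConfig, design: PairedDesign
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Lognormal mIHC densities; immune markers get the ADC excess in tumor regions."""
    rng = _rng(config, "densities")
    rows = []
    means: dict[str, float] = {}
    for marker in _DENSITY_MARKERS:
        for region in ("tumor", "stroma"):
            base = _DENSITY_BASELINE_LOG[marker] - (0.5 if region == "stroma" else 0.0)
            for histology in ("ADC", "SQCC"):
                mean_log = base
                if histology == "ADC" and marker in _IMMUNE_DENSITY_MARKERS:
                    mean_log += config.density_effect
                means[f"{marker}|{region}|{histology}"] = mean_log
    for sample in design.samples:
        histology = design.histology_of(sample)
        for marker in _DENSITY_MARKERS:
            for region in ("tumor", "stroma"):
                mean_log = means[f"{marker}|{region}|{histology}"]
                rows.append(
                    {
                        "sample": sample,
                        "marker": marker,
                        "region": region,
                        "density": float(rng.lognormal(mean_log, 0.4)),
                    }
                )
    return pd.DataFrame(rows), means


def default_design(n_patients: int) -> PairedDesign:
    """P1..Pn, each with lesions P*_AD and P*_SQ."""
    patients = [f"P{i + 1}" for i in range(n_patients)]
    return PairedDesign(
        patients=tuple(patients),
        adc_sample=tuple(f"{p}_AD" for p in patients),
        sqcc_sample=tuple(f"{p}_SQ" for p in patients),
    )


def simulate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate a full paired cohort; deterministic for a fixed master seed."""
    config = config or CohortConfig()
    design = default_design(config.n_patients)
    counts, lengths, latent, de_status = simulate_expression(config, design)
    variants, neoantigens = simulate_variants(config, design)
    genotypes, evidence, loh_truth = simulate_hla(config, design)
    densities, density_means = simulate_densities(config, design)
    truth = TruthRecord(
        latent_infiltration=latent,
        loh_status=loh_truth,
        de_status=de_status,
        density_means=density_means,
    )
    return CohortBundle(
        counts=counts,
        gene_lengths=lengths,
        variants=variants,
        neoantigen_counts=neoantigens,
        hla_genotypes=genotypes,
        hla_evidence=evidence,
        densities=densities,
        design=design,
        truth=truth,
        config=config,
    )


def write_bundle(bundle: CohortBundle, directory: str | Path) -> dict[str, Path]:
    """Persist a bundle as plain-text files that round-trip through the io layer."""
    from . import io as tpio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["counts"] = directory / "counts.tsv"
    tpio.write_matrix_tsv(bundle.counts, paths["counts"])
    paths["lengths"] = directory / "gene_lengths.tsv"
    tpio.write_lengths_tsv(bundle.gene_lengths, paths["lengths"])
    for lesion, records in bundle.variants.items():
        key = f"variants_{lesion}"
        paths[key] = directory / f"{lesion}.vcf"
        tpio.write_variant_vcf(records, paths[key])
    paths["neoantigens"] = directory / "neoantigen_counts.tsv"
    pd.Series(bundle.neoantigen_counts, name="n_neoantigens").rename_axis("lesion").to_csv(
        paths["neoantigens"], sep="\t"
    )
    paths["hla_genotypes"] = directory / "hla_genotypes.tsv"
    tpio.write_genotypes_tsv(bundle.hla_genotypes, paths["hla_genotypes"])
    paths["hla_evidence"] = directory / "hla_evidence.tsv"
    tpio.write_evidence_tsv(bundle.hla_evidence, paths["hla_evidence"])
    paths["densities"] = directory / "densities.tsv"
    tpio.write_densities_tsv(bundle.densities, paths["densities"])
    paths["pairing"] = directory / "pairing.tsv"
    tpio.write_pairing_tsv(bundle.design, paths["pairing"])
    paths["panel"] = directory / "til_panel.gmt"
    tpio.write_gmt(bundle.config.marker_panel.populations, paths["panel"])
    paths["signatures"] = directory / "immune_signatures.gmt"
    tpio.write_gmt(bundle.config.signature_sets.characteristics, paths["signatures"])
    paths["truth"] = directory / "truth.json"
    paths["truth"].write_text(bundle.truth.to_json())
    return paths
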