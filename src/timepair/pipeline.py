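"""End-to-end orchestration: variants -> burden -> HLA-LOH -> normalization
-> TIME scoring -> paired comparisons, with a persisted cohort report.

Two entry points: :func:`analyze_bundle` runs the whole flow on an
in-memory :class:`~timepair.simulate.CohortBundle`, and
:func:`run_pipeline` is the file-driven equivalent (validate config,
load the bundle from disk, analyze, persist every stage output).
Re-running with identical config and inputs reproduces all numeric
outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as tpio
from .compare import compare_all
from .design import PairedDesign
from .errors import ConfigurationError
from .expression import counts_to_tpm, deg_table, log2_normalize, paired_deg_filter
from .hla import call_lesion_loh, summarize_loh
from .matrix import ExpressionMatrix
from .scoring import (
    MarkerPanel,
    SignatureSet,
    anchor_expression,
    compute_cell_scores,
    compute_enrichment_scores,
    compute_signature_scores,
    compute_til_score,
)
from .simulate import CohortBundle
from .variants import MAD_SCALE, FilterThresholds, lesion_burden

logger = logging.getLogger("timepair")

DEFAULT_EXONIC_BASES = 5e7  # V6-class whole-exome capture


@dataclass
class RunConfig:
    """File paths and threshold overrides for a file-driven run."""

    bundle_dir: str
    output_dir: str
    exonic_bases: float = DEFAULT_EXONIC_BASES
    loh_alpha: float = 0.01
    r_threshold: float = 0.6
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    pseudocount: float = 1.0
    math_scale: float = MAD_SCALE
    anchor_gene: str = "PTPRC"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exonic_bases <= 0:
            raise ConfigurationError(f"exonic_bases must be positive, got {self.exonic_bases}")
        if not 0 < self.loh_alpha < 1:
            raise ConfigurationError(f"loh_alpha must lie in (0, 1), got {self.loh_alpha}")
        if not 0 < self.p_threshold < 1:
            raise ConfigurationError(f"p_threshold must lie in (0, 1), got {self.p_threshold}")
        if self.pseudocount <= 0:
            raise ConfigurationError(f"pseudocount must be positive, got {self.pseudocount}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CohortReport:
    """All stage outputs of one cohort run plus a provenance block."""

    burden: pd.DataFrame
    loh_calls: list
    loh_summary: dict
    cell_scores: pd.DataFrame
    til_scores: pd.Series
    included_populations: set
    anchor_correlations: dict
    enrichment_scores: pd.DataFrame
    signature_scores: pd.DataFrame
    degs: pd.DataFrame
    comparisons: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _load_bundle_dir(directory: Path) -> CohortBundle:
    """Read a written bundle back into memory (inverse of write_bundle)."""
    from .simulate import CohortConfig, TruthRecord

    design = tpio.read_pairing_tsv(directory / "pairing.tsv")
    counts = tpio.read_counts_tsv(directory / "counts.tsv")
    lengths = tpio.read_lengths_tsv(directory / "gene_lengths.tsv")
    variants = {
        lesion: tpio.read_variant_vcf(directory / f"{lesion}.vcf") for lesion in design.samples
    }
    neo = pd.read_csv(directory / "neoantigen_counts.tsv", sep="\t", index_col="lesion")
    neoantigens = {str(k): int(v) for k, v in neo["n_neoantigens"].items()}
    panel = MarkerPanel(populations=tpio.read_gmt(directory / "til_panel.gmt"))
    signatures = SignatureSet(characteristics=tpio.read_gmt(directory / "immune_signatures.gmt"))
    truth_path = directory / "truth.json"
    truth = None
    if truth_path.exists():
        raw = json.loads(truth_path.read_text())
        truth = TruthRecord(**raw)
    return CohortBundle(
        counts=counts,
        gene_lengths=lengths,
        variants=variants,
        neoantigen_counts=neoantigens,
        hla_genotypes=tpio.read_genotypes_tsv(directory / "hla_genotypes.tsv"),
        hla_evidence=tpio.read_evidence_tsv(directory / "hla_evidence.tsv"),
        densities=tpio.read_densities_tsv(directory / "densities.tsv"),
        design=design,
        truth=truth,
        config=CohortConfig(marker_panel=panel, signature_sets=signatures),
    )


def burden_table(
    bundle: CohortBundle,
    exonic_bases: float = DEFAULT_EXONIC_BASES,
    math_scale: float = MAD_SCALE,
    thresholds: FilterThresholds | None = None,
) -> pd.DataFrame:
    """Per-lesion burden metrics (rows = lesions)."""
    rows = {}
    for lesion in bundle.design.samples:
        result = lesion_burden(
            bundle.variants[lesion],
            exonic_bases=exonic_bases,
            n_neoantigens=bundle.neoantigen_counts.get(lesion, 0),
            thresholds=thresholds,
            scale_constant=math_scale,
        )
        rows[lesion] = {
            "tmb": result.tmb,
            "tnb": result.tnb,
            "math": result.math_score,
            "n_variants_pass": result.n_variants_pass,
        }
    return pd.DataFrame(rows).T.rename_axis("lesion")


def density_metrics(densities: pd.DataFrame, region: str = "tumor") -> pd.DataFrame:
    """Pivot the tidy density table into samples x density_<marker> columns."""
    sub = densities[densities["region"] == region]
    wide = sub.pivot(index="sample", columns="marker", values="density")
    wide.columns = [f"density_{m}_{region}" for m in wide.columns]
    return wide


def analyze_bundle(
    bundle: CohortBundle,
    exonic_bases: float = DEFAULT_EXONIC_BASES,
    loh_alpha: float = 0.01,
    r_threshold: float = 0.6,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    pseudocount: float = 1.0,
    math_scale: float = MAD_SCALE,
    provenance: dict | None = None,
) -> CohortReport:
    """Run every analysis stage on an in-memory cohort bundle."""
    design = bundle.design
    panel = bundle.config.marker_panel
    signatures = bundle.config.signature_sets

    logger.info("stage variants/burden: %d lesions", len(design.samples))
    burden = burden_table(bundle, exonic_bases=exonic_bases, math_scale=math_scale)

    logger.info("stage hla-loh")
    loh_calls = call_lesion_loh(bundle.hla_evidence, alpha=loh_alpha)
    loh_summary = summarize_loh(loh_calls, design)

    logger.info("stage normalization")
    tpm = counts_to_tpm(bundle.counts, bundle.gene_lengths)
    log_expr = log2_normalize(tpm, pseudocount=pseudocount)

    logger.info("stage scoring")
    cell_scores = compute_cell_scores(log_expr, panel)
    til = compute_til_score(
        cell_scores, anchor_expression(log_expr, panel.anchor_gene), r_threshold=r_threshold
    )
    enrichment = compute_enrichment_scores(cell_scores, til)
    signature_scores = compute_signature_scores(log_expr, signatures)

    logger.info("stage deg")
    degs = deg_table(
        paired_deg_filter(log_expr, design, lfc_threshold=lfc_threshold, p_threshold=p_threshold)
    )

    logger.info("stage comparisons")
    metrics = pd.concat(
        [
            burden[["tmb", "tnb", "math"]],
            pd.DataFrame({"til_score": til.til_score}),
            cell_scores.T,
            signature_scores.T,
            density_metrics(bundle.densities),
        ],
        axis=1,
    )
    comparisons = compare_all(metrics, design)

    return CohortReport(
        burden=burden,
        loh_calls=loh_calls,
        loh_summary=loh_summary,
        cell_scores=cell_scores,
        til_scores=til.til_score,
        included_populations=til.included_populations,
        anchor_correlations=til.correlations,
        enrichment_scores=enrichment,
        signature_scores=signature_scores,
        degs=degs,
        comparisons=comparisons,
        provenance=provenance or {},
    )


def write_report(report: CohortReport, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    report.burden.to_csv(directory / "burden.tsv", sep="\t", float_format="%.9g")
    loh_rows = pd.DataFrame(
        [
            {
                "lesion": c.lesion,
                "locus": c.locus.value,
                "lost_allele": c.lost_allele,
                "copy_estimate": c.copy_estimate,
                "imbalance_p": c.imbalance_p,
                "is_loh": c.is_loh,
                "applicable": c.applicable,
            }
            for c in report.loh_calls
        ]
    )
    loh_rows.to_csv(directory / "loh_calls.tsv", sep="\t", index=False, float_format="%.6g")
    summary = {k: v for k, v in report.loh_summary.items() if k != "lesion_status"}
    summary["lesion_status"] = report.loh_summary["lesion_status"]
    (directory / "loh_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    report.cell_scores.to_csv(directory / "cell_scores.tsv", sep="\t", float_format="%.9g")
    report.til_scores.to_csv(directory / "til_scores.tsv", sep="\t", float_format="%.9g")
    report.enrichment_scores.to_csv(
        directory / "enrichment_scores.tsv", sep="\t", float_format="%.9g"
    )
    report.signature_scores.to_csv(
        directory / "signature_scores.tsv", sep="\t", float_format="%.9g"
    )
    report.degs.to_csv(directory / "degs.tsv", sep="\t", index=False, float_format="%.9g")
    report.comparisons.to_csv(
        directory / "comparisons.tsv", sep="\t", index=False, float_format="%.9g"
    )
    (directory / "provenance.json").write_text(json.dumps(report.provenance, indent=2))


def run_pipeline(config: RunConfig) -> CohortReport:
    """File-driven end-to-end run: validate, load, analyze, persist.

    Any stage error aborts with the stage name; outputs written so far
    are retained next to a FAILED marker.
    """
    bundle_dir = Path(config.bundle_dir)
    required = ["pairing.tsv", "counts.tsv", "gene_lengths.tsv", "hla_evidence.tsv",
                "densities.tsv", "neoantigen_counts.tsv", "til_panel.gmt",
                "immune_signatures.gmt"]
    missing = [name for name in required if not (bundle_dir / name).exists()]
    if missing:
        raise ConfigurationError(f"bundle directory {bundle_dir} missing inputs: {missing}")

    provenance = {
        "timepair_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "bundle_dir": str(bundle_dir),
    }
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        bundle = _load_bundle_dir(bundle_dir)
        report = analyze_bundle(
            bundle,
            exonic_bases=config.exonic_bases,
            loh_alpha=config.loh_alpha,
            r_threshold=config.r_threshold,
            lfc_threshold=config.lfc_threshold,
            p_threshold=config.p_threshold,
            pseudocount=config.pseudocount,
            math_scale=config.math_scale,
            provenance=provenance,
        )
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    write_report(report, out_dir)
    return report
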