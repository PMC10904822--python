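"""Replicated-cohort experiments: power, calibration, and caller operating
characteristics.

These routines drive the synthetic generator and the analysis stages at
their default study conditions over many seeded replicates. They back
the package's self-checks and the reproduction script; they are also
useful for planning (e.g. how often a five-pair design detects a given
infiltration effect).
"""

from __future__ import annotations

import numpy as np

from .compare import CompDirection, paired_t_test
from .errors import ValidationError
from .expression import counts_to_tpm, log2_normalize, paired_deg_filter
from .hla import HlaAlleleEvidence, HlaLocus, call_hla_loh
from .scoring import anchor_expression, compute_cell_scores, compute_til_score
from .simulate import CohortConfig, simulate_cohort


def til_comparison(bundle, r_threshold: float = 0.6):
    """The pipeline's TIL-score arm on one bundle: normalize, score, gate, compare.

    Returns the ComparisonResult, or None when no population passes the
    anchor-correlation gate (a cohort on which the method makes no call).
    """
    log_expr = log2_normalize(counts_to_tpm(bundle.counts, bundle.gene_lengths))
    cell_scores = compute_cell_scores(log_expr, bundle.config.marker_panel)
    try:
        til = compute_til_score(
            cell_scores,
            anchor_expression(log_expr, bundle.config.marker_panel.anchor_gene),
            r_threshold=r_threshold,
        )
    except ValidationError:
        return None
    x = til.til_score[list(bundle.design.adc_sample)]
    y = til.til_score[list(bundle.design.sqcc_sample)]
    return paired_t_test(list(x), list(y), metric="til_score")


def til_recovery_rate(
    n_cohorts: int, effect: float = 1.5, base_seed: int = 0, alpha: float = 0.05
) -> float:
    """Fraction of cohorts where the TIL comparison detects ADC > SQCC.

    Detection = direction higher_in_adc with two-sided p < alpha. A
    cohort with an empty correlation gate counts as a non-detection.
    """
    hits = 0
    for k in range(n_cohorts):
        bundle = simulate_cohort(
            CohortConfig(infiltration_effect=effect, master_seed=base_seed + k)
        )
        result = til_comparison(bundle)
        if (
            result is not None
            and result.direction is CompDirection.HIGHER_IN_ADC
            and result.p_value < alpha
        ):
            hits += 1
    return hits / n_cohorts


def til_null_rejection_rate(n_cohorts: int, base_seed: int = 0, alpha: float = 0.05) -> float:
    """Two-sided rejection rate of the TIL comparison with no planted effect."""
    rejections = 0
    for k in range(n_cohorts):
        bundle = simulate_cohort(
            CohortConfig(infiltration_effect=0.0, density_effect=0.0, master_seed=base_seed + k)
        )
        result = til_comparison(bundle)
        if result is not None and not result.degenerate and result.p_value < alpha:
            rejections += 1
    return rejections / n_cohorts


def loh_false_positive_rate(
    n_loci: int, seed: int = 0, alpha: float = 0.01, mean_reads: int = 300
) -> float:
    """LOH call rate on balanced heterozygous loci (copies ~ 1, reads 50:50)."""
    rng = np.random.default_rng(seed)
    calls = 0
    for _ in range(n_loci):
        total = max(int(rng.poisson(mean_reads)), 10)
        reads1 = int(rng.binomial(total, 0.5))
        copy1 = float(max(rng.normal(1.0, 0.05), 0.55))
        copy2 = float(max(rng.normal(1.0, 0.05), 0.55))
        pair = (
            HlaAlleleEvidence("L", HlaLocus.A, "A*01:01", reads1, copy1),
            HlaAlleleEvidence("L", HlaLocus.A, "A*02:01", total - reads1, copy2),
        )
        if call_hla_loh(pair, alpha=alpha).is_loh:
            calls += 1
    return calls / n_loci


def loh_sensitivity(
    n_loci: int,
    seed: int = 0,
    alpha: float = 0.01,
    minor_copy: float = 0.2,
    major_copy: float = 1.0,
    min_reads: int = 200,
) -> float:
    """LOH detection rate on true-loss loci (minor copy 0.2, >= 200 unique reads)."""
    rng = np.random.default_rng(seed)
    p_minor = minor_copy / (minor_copy + major_copy)
    hits = 0
    for _ in range(n_loci):
        total = int(rng.integers(min_reads, 2 * min_reads))
        reads1 = int(rng.binomial(total, p_minor))
        pair = (
            HlaAlleleEvidence("L", HlaLocus.A, "A*01:01", reads1, minor_copy),
            HlaAlleleEvidence("L", HlaLocus.A, "A*02:01", total - reads1, major_copy),
        )
        if call_hla_loh(pair, alpha=alpha).is_loh:
            hits += 1
    return hits / n_loci


def deg_null_pass_fraction(
    n_reps: int, n_genes: int = 2000, n_pairs: int = 5, base_seed: int = 0
) -> float:
    """Mean fraction of genes passing the DEG thresholds with no planted effect."""
    fractions = []
    for k in range(n_reps):
        bundle = simulate_cohort(
            CohortConfig(
                n_patients=n_pairs,
                n_genes=n_genes,
                infiltration_effect=0.0,
                n_planted_de=0,
                master_seed=base_seed + k,
            )
        )
        log_expr = log2_normalize(counts_to_tpm(bundle.counts, bundle.gene_lengths))
        records = paired_deg_filter(log_expr, bundle.design)
        fractions.append(len(records) / len(log_expr.genes))
    return float(np.mean(fractions))
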