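"""TPM normalization, log2 transform, and the paired differential-expression filter.

The DEG stage is a paired-design screen on log2(TPM + 1): per gene the
log2 fold change is the mean over patients of (SQCC - ADC) log2 values
and the p value comes from a paired t-test on those within-patient
differences. Genes are retained at |log2FC| > 1 and p < 0.05 (both
strict). This thresholding rule — not any particular count-model
machinery — is the contract; the orientation (SQCC relative to ADC) and
the pseudocount are recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import PairedDesign
from .errors import DesignError, ValidationError
from .matrix import ExpressionMatrix, Unit


class Direction(str, Enum):
    UP_IN_SQCC = "up_in_sqcc"
    DOWN_IN_SQCC = "down_in_sqcc"


@dataclass(frozen=True)
class DegRecord:
    gene: str
    log2fc: float
    p_value: float
    p_adjusted: float
    direction: Direction


def counts_to_tpm(counts: ExpressionMatrix, gene_lengths: dict[str, float]) -> ExpressionMatrix:
    """Convert raw counts to transcripts per million.

    Per column: rate_g = count_g / length_g, tpm_g = rate_g / sum(rates)
    * 1e6, so every column sums to one million. Gene lengths are in base
    pairs and must be positive for every gene in the matrix.
    """
    counts.require_unit(Unit.COUNTS)
    lengths = []
    for gene in counts.genes:
        length = gene_lengths.get(gene)
        if length is None:
            raise ValidationError(f"no gene length for {gene!r}")
        if length <= 0:
            raise ValidationError(f"non-positive length for gene {gene!r}: {length}")
        lengths.append(float(length))
    rates = counts.values.div(pd.Series(lengths, index=counts.genes), axis=0)
    col_sums = rates.sum(axis=0)
    zero_cols = col_sums.index[col_sums <= 0].tolist()
    if zero_cols:
        raise ValidationError(f"all-zero columns have undefined TPM: {zero_cols}")
    tpm = rates.div(col_sums, axis=1) * 1e6
    meta = dict(counts.meta)
    return ExpressionMatrix(values=tpm, unit=Unit.TPM, meta=meta)


def log2_normalize(tpm: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount), the representation all scoring stages use."""
    tpm.require_unit(Unit.TPM)
    if pseudocount <= 0:
        raise ValidationError(f"pseudocount must be positive, got {pseudocount}")
    values = np.log2(tpm.values + pseudocount)
    meta = dict(tpm.meta)
    meta["pseudocount"] = pseudocount
    return ExpressionMatrix(values=values, unit=Unit.LOG2TPM, meta=meta)


def paired_log2fc(
    log_expr: ExpressionMatrix, design: PairedDesign
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Per-gene within-patient differences (SQCC - ADC), their mean, and paired-t p.

    Returns (diffs genes x patients, log2fc, p). Vectorized over genes;
    genes whose differences have zero variance get p = NaN.
    """
    missing = [s for s in design.samples if s not in log_expr.samples]
    if missing:
        raise DesignError(f"design samples absent from the matrix: {missing}")
    if design.n_pairs < 3:
        raise DesignError(f"paired DEG analysis requires >= 3 pairs, got {design.n_pairs}")
    sq = log_expr.values[list(design.sqcc_sample)].to_numpy()
    ad = log_expr.values[list(design.adc_sample)].to_numpy()
    diffs = sq - ad
    log2fc = diffs.mean(axis=1)
    n = design.n_pairs
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[sd == 0] = np.nan
    diffs_df = pd.DataFrame(diffs, index=log_expr.genes, columns=design.patients)
    return (
        diffs_df,
        pd.Series(log2fc, index=log_expr.genes, name="log2fc"),
        pd.Series(p, index=log_expr.genes, name="p_value"),
    )


def paired_deg_filter(
    log_expr: ExpressionMatrix,
    design: PairedDesign,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> list[DegRecord]:
    """Retain genes with |log2FC| > lfc_threshold AND p < p_threshold (strict).

    log2FC is oriented SQCC minus ADC; p is the raw paired-t p (the
    retention rule uses raw p), with a Benjamini-Hochberg adjusted p
    carried alongside for reporting.
    """
    _, log2fc, p = paired_log2fc(log_expr, design)
    valid = p.notna()
    padj = pd.Series(np.nan, index=p.index)
    if valid.any():
        padj[valid] = multipletests(p[valid].to_numpy(), method="fdr_bh")[1]
    keep = valid & (log2fc.abs() > lfc_threshold) & (p < p_threshold)
    records = [
        DegRecord(
            gene=gene,
            log2fc=float(log2fc[gene]),
            p_value=float(p[gene]),
            p_adjusted=float(padj[gene]),
            direction=Direction.UP_IN_SQCC if log2fc[gene] > 0 else Direction.DOWN_IN_SQCC,
        )
        for gene in log_expr.genes
        if keep[gene]
    ]
    return records


def deg_table(records: list[DegRecord]) -> pd.DataFrame:
    """Tidy DEG table (gene, log2fc, p, padj, direction)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "log2fc": r.log2fc,
                "p": r.p_value,
                "padj": r.p_adjusted,
                "direction": r.direction.value,
            }
            for r in records
        ],
        columns=["gene", "log2fc", "p", "padj", "direction"],
    )
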