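"""Co-expression scoring of tumor-infiltrating lymphocytes and immune characteristics.

The scoring scheme works entirely on log2-normalized bulk expression:

* a *cell score* for each of 14 immune populations is the mean
  log2-normalized expression of that population's marker genes;
* the total *TIL score* per sample is the mean of all cell scores whose
  correlation with the pan-leukocyte anchor gene PTPRC (CD45) across
  samples exceeds 0.6 — the correlation gate keeps only populations
  whose signal tracks overall leukocyte content;
* *enrichment scores* are the per-population residuals of regressing
  each cell score on the TIL score (OLS with intercept), i.e. abundance
  or depletion of a population relative to total infiltration;
* *signature scores* summarize nine immune-characteristic gene sets
  (checkpoints, chemokines, MHC machinery, ...) by per-sample mean
  (default) or sum of their genes' log2-normalized expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .matrix import ExpressionMatrix, Unit

DEFAULT_ANCHOR = "PTPRC"
DEFAULT_R_THRESHOLD = 0.6


def _read_gmt_resource(name: str) -> dict[str, list[str]]:
    from .io import parse_gmt_lines

    ref = resources.files("timepair.resources").joinpath(name)
    with ref.open("r") as handle:
        return parse_gmt_lines(handle, filename=name)


@dataclass
class MarkerPanel:
    """Named marker-gene lists for the immune populations, plus the anchor gene.

    The anchor (default PTPRC/CD45) is used only for the TIL correlation
    gate and may not itself appear inside any population list.
    """

    populations: dict[str, list[str]]
    anchor_gene: str = DEFAULT_ANCHOR

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValidationError("panel must define at least one population")
        for name, genes in self.populations.items():
            if not genes:
                raise ValidationError(f"population {name!r} has an empty gene list")
            if self.anchor_gene in genes:
                raise ValidationError(
                    f"anchor gene {self.anchor_gene!r} may not be a member of "
                    f"population {name!r}"
                )

    @classmethod
    def default(cls) -> "MarkerPanel":
        """Bundled 14-population panel in the co-expression score style."""
        return cls(populations=_read_gmt_resource("til_panel.gmt"))

    @classmethod
    def from_gmt(cls, path, anchor_gene: str = DEFAULT_ANCHOR) -> "MarkerPanel":
        from .io import read_gmt

        return cls(populations=read_gmt(path), anchor_gene=anchor_gene)

    @property
    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.populations.values():
            for g in genes:
                seen.setdefault(g)
        return list(seen)


@dataclass
class SignatureSet:
    """Named immune-characteristic gene sets (default: nine categories)."""

    characteristics: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.characteristics:
            raise ValidationError("signature set must define at least one characteristic")
        for name, genes in self.characteristics.items():
            if not genes:
                raise ValidationError(f"characteristic {name!r} has an empty gene list")

    @classmethod
    def default(cls) -> "SignatureSet":
        return cls(characteristics=_read_gmt_resource("immune_signatures.gmt"))

    @classmethod
    def from_gmt(cls, path) -> "SignatureSet":
        from .io import read_gmt

        return cls(characteristics=read_gmt(path))

    @property
    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.characteristics.values():
            for g in genes:
                seen.setdefault(g)
        return list(seen)


@dataclass
class TilScoreResult:
    til_score: pd.Series
    included_populations: set[str]
    correlations: dict[str, float]
    warnings: list[str] = field(default_factory=list)


def _resolve_genes(
    name: str, genes: list[str], available: set[str], strict: bool, warn_records: list[str]
) -> list[str]:
    present = [g for g in genes if g in available]
    missing = [g for g in genes if g not in available]
    if missing:
        msg = f"{name}: {len(missing)} marker gene(s) absent from the matrix: {missing}"
        if strict:
            raise ValidationError(msg)
        warn_records.append(msg)
        warnings.warn(msg, stacklevel=3)
    if not present:
        raise ValidationError(f"{name}: no resolvable marker genes in the matrix")
    return present


def compute_cell_scores(
    log_expr: ExpressionMatrix, panel: MarkerPanel, strict: bool = False
) -> pd.DataFrame:
    """Populations x samples table of mean marker log2-normalized expression.

    Missing marker genes are dropped with a warning (``strict=True``
    errors instead); a population with no resolvable genes always errors.
    """
    log_expr.require_unit(Unit.LOG2TPM)
    available = set(log_expr.genes)
    warn_records: list[str] = []
    rows = {}
    for name, genes in panel.populations.items():
        present = _resolve_genes(name, genes, available, strict, warn_records)
        rows[name] = log_expr.values.loc[present].mean(axis=0)
    scores = pd.DataFrame(rows).T
    scores.index.name = "population"
    return scores


def compute_til_score(
    cell_scores: pd.DataFrame,
    anchor_expr: pd.Series,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    method: str = "pearson",
) -> TilScoreResult:
    """Gate populations on correlation with the anchor, then average them.

    For each population the correlation of its score vector with the
    anchor expression vector across samples is computed (Pearson by
    default, Spearman optional); populations with r strictly above the
    threshold enter the TIL score, which is their per-sample mean score.
    Zero-variance score or anchor vectors yield an undefined correlation:
    the population is excluded with a warning record. If no population
    passes the gate an explicit error is raised.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    samples = list(cell_scores.columns)
    if len(samples) < 3:
        raise ValidationError(f"correlation gate requires >= 3 samples, got {len(samples)}")
    anchor = anchor_expr.reindex(samples)
    if anchor.isna().any():
        raise ValidationError("anchor expression missing for some scored samples")
    anchor_arr = anchor.to_numpy(dtype=float)

    correlations: dict[str, float] = {}
    warn_records: list[str] = []
    included: set[str] = set()
    anchor_degenerate = float(np.std(anchor_arr)) == 0.0
    for name in cell_scores.index:
        vec = cell_scores.loc[name].to_numpy(dtype=float)
        if anchor_degenerate or float(np.std(vec)) == 0.0:
            correlations[name] = float("nan")
            warn_records.append(f"{name}: zero-variance vector, correlation undefined; excluded")
            continue
        if method == "pearson":
            r = float(stats.pearsonr(vec, anchor_arr).statistic)
        else:
            r = float(stats.spearmanr(vec, anchor_arr).statistic)
        correlations[name] = r
        if r > r_threshold:
            included.add(name)
    if not included:
        raise ValidationError(
            f"no population passed the anchor-correlation gate (r > {r_threshold})"
        )
    til = cell_scores.loc[sorted(included)].mean(axis=0)
    til.name = "til_score"
    return TilScoreResult(
        til_score=til,
        included_populations=included,
        correlations=correlations,
        warnings=warn_records,
    )


def compute_enrichment_scores(cell_scores: pd.DataFrame, til: TilScoreResult) -> pd.DataFrame:
    """Residuals of each population's score regressed on the TIL score.

    Simple per-population OLS with intercept across samples; residuals
    measure abundance or depletion of a population relative to total
    infiltration. Errors if the TIL score is constant (degenerate fit).
    """
    x = til.til_score.reindex(cell_scores.columns).to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("til_score undefined for some samples")
    if float(np.std(x)) == 0.0:
        raise ValidationError("til_score is constant across samples; regression degenerate")
    design = np.column_stack([np.ones_like(x), x])
    y = cell_scores.to_numpy(dtype=float).T  # samples x populations
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = (y - design @ coef).T
    out = pd.DataFrame(residuals, index=cell_scores.index, columns=cell_scores.columns)
    out.index.name = "population"
    return out


def compute_signature_scores(
    log_expr: ExpressionMatrix,
    signatures: SignatureSet,
    mode: str = "mean",
    strict: bool = False,
) -> pd.DataFrame:
    """Characteristics x samples matrix of signature scores.

    ``mode='mean'`` (default) scores each characteristic as the mean of
    its genes' log2-normalized expression, keeping signature scores on
    the same scale as cell scores; ``mode='sum'`` uses the sum. The mode
    is recorded in the result's attrs.
    """
    log_expr.require_unit(Unit.LOG2TPM)
    if mode not in ("mean", "sum"):
        raise ValidationError(f"unknown aggregation mode {mode!r}")
    available = set(log_expr.genes)
    warn_records: list[str] = []
    rows = {}
    for name, genes in signatures.characteristics.items():
        present = _resolve_genes(name, genes, available, strict, warn_records)
        block = log_expr.values.loc[present]
        rows[name] = block.mean(axis=0) if mode == "mean" else block.sum(axis=0)
    scores = pd.DataFrame(rows).T
    scores.index.name = "characteristic"
    scores.attrs["mode"] = mode
    return scores


def anchor_expression(log_expr: ExpressionMatrix, anchor_gene: str = DEFAULT_ANCHOR) -> pd.Series:
    """The anchor gene's log2-normalized expression across samples."""
    log_expr.require_unit(Unit.LOG2TPM)
    if anchor_gene not in log_expr.values.index:
        raise ValidationError(f"anchor gene {anchor_gene!r} absent from the matrix")
    return log_expr.values.loc[anchor_gene]
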