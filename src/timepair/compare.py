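"""Paired ADC-vs-SQCC comparison of any per-sample metric.

Two tests are provided, mirroring the statistical conventions of paired
tumor-lesion studies: a two-sided paired t-test (expression-derived
scores, cell densities) and the Wilcoxon signed-rank test with an EXACT
two-sided p value for n <= 25 pairs (burden metrics). With only five
pairs the exact signed-rank null is very coarse — its smallest
attainable two-sided p is 2/2^5 = 0.0625 — which is why the default
test policy sends continuous scores to the paired t-test.

Convention throughout: ``x`` holds the ADC values and ``y`` the SQCC
values, pair-aligned by patient; a positive mean/median difference
reports direction ``higher_in_adc``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import PairedDesign
from .errors import ValidationError

EXACT_MAX_N = 25


class TestKind(str, Enum):
    PAIRED_T = "paired_t"
    WILCOXON_SIGNED_RANK = "wilcoxon_signed_rank"


class CompDirection(str, Enum):
    HIGHER_IN_ADC = "higher_in_adc"
    HIGHER_IN_SQCC = "higher_in_sqcc"
    NONE = "none"


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    n_pairs: int
    statistic: float
    p_value: float
    test: TestKind
    direction: CompDirection
    degenerate: bool = False


@dataclass(frozen=True)
class DensityRecord:
    """One mIHC cell-density measurement (cells per mm^2)."""

    sample: str
    marker: str
    region: str
    density: float

    def __post_init__(self) -> None:
        if self.region not in ("tumor", "stroma", "total"):
            raise ValidationError(f"unknown region {self.region!r}")
        if self.density < 0:
            raise ValidationError(f"density must be >= 0, got {self.density}")


def _check_pairs(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError(f"unequal lengths: {xa.size} vs {ya.size}")
    if xa.size < 2:
        raise ValidationError(f"paired tests require >= 2 pairs, got {xa.size}")
    return xa, ya


def _direction(center_diff: float) -> CompDirection:
    if center_diff > 0:
        return CompDirection.HIGHER_IN_ADC
    if center_diff < 0:
        return CompDirection.HIGHER_IN_SQCC
    return CompDirection.NONE


def paired_t_test(x: Sequence[float], y: Sequence[float], metric: str = "") -> ComparisonResult:
    """Two-sided paired t-test on the per-patient differences x - y.

    Zero-variance differences (including x == y) give a degenerate
    result with an undefined p rather than an exception.
    """
    xa, ya = _check_pairs(x, y)
    d = xa - ya
    if float(np.std(d, ddof=0)) == 0.0:
        return ComparisonResult(
            metric=metric,
            n_pairs=d.size,
            statistic=float("nan"),
            p_value=float("nan"),
            test=TestKind.PAIRED_T,
            direction=_direction(float(d.mean())),
            degenerate=True,
        )
    res = stats.ttest_rel(xa, ya)
    return ComparisonResult(
        metric=metric,
        n_pairs=d.size,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test=TestKind.PAIRED_T,
        direction=_direction(float(d.mean())),
    )


def signed_rank_exact_p(w_plus: float, ranks: Sequence[float]) -> float:
    """Exact two-sided p of the signed-rank statistic by full-null convolution.

    ``ranks`` are the (mid)ranks of the non-zero |differences|; the null
    assigns each rank a positive sign independently with probability 1/2.
    The distribution of W+ is built by dynamic programming over doubled
    ranks (midranks are half-integers), which enumerates the same 2^n
    sign assignments as brute force. p = 2 * min(P(W+ <= w), P(W+ >= w)),
    capped at 1.
    """
    doubled = [int(round(2 * r)) for r in ranks]
    if any(abs(2 * r - d) > 1e-9 for r, d in zip(ranks, doubled)):
        raise ValidationError("ranks must be integers or half-integers")
    total = sum(doubled)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for d in doubled:
        shifted = np.zeros_like(counts)
        shifted[d:] = counts[: counts.size - d]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    lower = counts[: w2 + 1].sum()
    upper = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    metric: str = "",
    zero_method: str = "wilcox",
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on pairs (x, y).

    Exact null distribution (full sign-assignment enumeration via
    convolution) for n <= 25 non-zero differences, normal approximation
    with tie correction above. Zero differences are discarded before
    ranking by default (``zero_method='wilcox'``); ``'pratt'`` keeps
    them in the ranking but excludes them from the statistic. Ties get
    midranks. All differences zero -> degenerate flagged result.
    """
    if zero_method not in ("wilcox", "pratt"):
        raise ValidationError(f"unknown zero_method {zero_method!r}")
    xa, ya = _check_pairs(x, y)
    d = xa - ya
    nonzero = d != 0
    if not nonzero.any():
        return ComparisonResult(
            metric=metric,
            n_pairs=d.size,
            statistic=float("nan"),
            p_value=float("nan"),
            test=TestKind.WILCOXON_SIGNED_RANK,
            direction=CompDirection.NONE,
            degenerate=True,
        )
    if zero_method == "wilcox":
        dd = d[nonzero]
        ranks = stats.rankdata(np.abs(dd))
    else:  # pratt: rank zeros too, then drop their ranks
        ranks_all = stats.rankdata(np.abs(d))
        dd = d[nonzero]
        ranks = ranks_all[nonzero]
    w_plus = float(ranks[dd > 0].sum())
    n = dd.size
    if n <= EXACT_MAX_N:
        p = signed_rank_exact_p(w_plus, ranks)
    else:
        mean = ranks.sum() / 2.0
        var = float(np.square(ranks).sum()) / 4.0
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(
        metric=metric,
        n_pairs=d.size,
        statistic=w_plus,
        p_value=p,
        test=TestKind.WILCOXON_SIGNED_RANK,
        direction=_direction(float(np.median(d))),
    )


#: Metric-name prefixes routed to the signed-rank test by the default policy.
BURDEN_METRICS = ("tmb", "tnb", "math")


def default_test_policy(metric: str) -> TestKind:
    """Burden metrics -> signed-rank; scores and densities -> paired t."""
    name = metric.lower()
    if any(name == b or name.startswith(b + "_") for b in BURDEN_METRICS):
        return TestKind.WILCOXON_SIGNED_RANK
    return TestKind.PAIRED_T


def compare_all(
    metrics: pd.DataFrame,
    design: PairedDesign,
    policy=default_test_policy,
) -> pd.DataFrame:
    """Run the paired ADC-vs-SQCC comparison for every metric column.

    ``metrics`` is a samples x metrics table (index = sample ids). Pairs
    in which either lesion lacks a value are dropped with a warning; the
    chosen test per metric comes from ``policy`` (metric name -> TestKind).
    Returns a tidy results table.
    """
    if metrics.empty:
        raise ValidationError("empty metric table")
    results = []
    for metric in metrics.columns:
        col = metrics[metric]
        x, y, dropped = [], [], []
        for patient, adc, sqcc in zip(design.patients, design.adc_sample, design.sqcc_sample):
            xv = col.get(adc, np.nan)
            yv = col.get(sqcc, np.nan)
            if pd.isna(xv) or pd.isna(yv):
                dropped.append(patient)
                continue
            x.append(float(xv))
            y.append(float(yv))
        if dropped:
            warnings.warn(
                f"{metric}: dropped {len(dropped)} pair(s) with missing values: {dropped}",
                stacklevel=2,
            )
        test = TestKind(policy(metric))
        if test is TestKind.WILCOXON_SIGNED_RANK:
            res = wilcoxon_signed_rank(x, y, metric=metric)
        else:
            res = paired_t_test(x, y, metric=metric)
        results.append(res)
    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "n_pairs": r.n_pairs,
                "statistic": r.statistic,
                "p": r.p_value,
                "test": r.test.value,
                "direction": r.direction.value,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )


def compute_density(cell_counts: int, area_mm2: float) -> float:
    """Cells per mm^2 from a raw count over a measured region area."""
    if area_mm2 <= 0:
        raise ValidationError(f"area must be positive, got {area_mm2}")
    if cell_counts < 0:
        raise ValidationError(f"cell count must be >= 0, got {cell_counts}")
    return cell_counts / area_mm2
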