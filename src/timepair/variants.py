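"""Somatic-variant filtering and tumor burden / heterogeneity metrics.

Implements the four-rule somatic filter used for FFPE tumor/normal exome
panels (non-silent consequence, VAF > 0.03, depth >= 50x, population
frequency < 0.01) and the three per-lesion summary statistics built on the
surviving variants:

* TMB — tumor mutational burden, mutations per megabase of captured exome;
* TNB — tumor neoantigen burden, predicted neoantigens per megabase
  (neoantigen counts are an upstream input, not predicted here);
* MATH — mutant-allele tumor heterogeneity, 100 x MAD(VAF) / median(VAF).

CNV gain/loss classification from absolute copy number is included because
it shares the thresholding character of the filter stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

#: MAD consistency constant for normally distributed data. The MATH
#: literature conventionally reports the scaled MAD; pass
#: ``scale_constant=1.0`` for the raw-MAD reading of the formula.
MAD_SCALE = 1.4826


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    SILENT = "silent"
    OTHER = "other"


#: Consequence classes counted as non-silent by the default filter.
NONSILENT = frozenset(
    {Consequence.MISSENSE, Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.SPLICE_SITE}
)


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant with the annotations the filter rules need."""

    chromosome: str
    position: int
    ref: str
    alt: str
    gene: str
    consequence_class: Consequence
    vaf: float
    depth: int
    population_frequency: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "consequence_class", Consequence(self.consequence_class))
        if self.position < 1:
            raise ValidationError(f"{self._tag()}: position must be >= 1, got {self.position}")
        # NaN marks a missing annotation: representable here, but rejected
        # by the filter stage rather than silently passed or failed
        if not math.isnan(self.vaf) and not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"{self._tag()}: vaf must lie in [0, 1], got {self.vaf}")
        if self.depth < 0:
            raise ValidationError(f"{self._tag()}: depth must be >= 0, got {self.depth}")
        if not math.isnan(self.population_frequency) and not (
            0.0 <= self.population_frequency <= 1.0
        ):
            raise ValidationError(
                f"{self._tag()}: population_frequency must lie in [0, 1], "
                f"got {self.population_frequency}"
            )

    def _tag(self) -> str:
        return f"variant {self.chromosome}:{self.position} {self.ref}>{self.alt}"


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the four-rule somatic filter.

    VAF and population frequency are strict inequalities; depth is
    inclusive. All defaults follow the tumor/normal exome convention for
    FFPE panels.
    """

    min_vaf: float = 0.03
    min_depth: int = 50
    max_popfreq: float = 0.01
    nonsilent_classes: frozenset = field(default_factory=lambda: NONSILENT)

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ConfigurationError(f"min_vaf must lie in [0, 1], got {self.min_vaf}")
        if not 0.0 <= self.max_popfreq <= 1.0:
            raise ConfigurationError(f"max_popfreq must lie in [0, 1], got {self.max_popfreq}")
        if self.min_depth < 0:
            raise ConfigurationError(f"min_depth must be >= 0, got {self.min_depth}")


@dataclass(frozen=True)
class BurdenResult:
    """Per-lesion burden summary (all rates are per megabase)."""

    tmb: float
    tnb: float
    math_score: float
    n_variants_pass: int


class CnvState(str, Enum):
    GAIN = "gain"
    LOSS = "loss"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class CnvCall:
    gene: str
    copy_number: float
    state: CnvState


def filter_somatic_variants(
    records: Iterable[VariantRecord], thresholds: FilterThresholds | None = None
) -> list[VariantRecord]:
    """Apply the four-rule somatic filter, preserving input order.

    A record survives iff its consequence class is non-silent AND
    vaf > min_vaf AND depth >= min_depth AND population frequency
    < max_popfreq. Records missing any annotation raise
    :class:`ValidationError` rather than silently passing or failing.
    """
    thresholds = thresholds or FilterThresholds()
    out: list[VariantRecord] = []
    for i, rec in enumerate(records):
        for fieldname in ("consequence_class", "vaf", "depth", "population_frequency"):
            value = getattr(rec, fieldname, None)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValidationError(f"record {i} ({rec._tag()}): missing annotation '{fieldname}'")
        keep = (
            rec.consequence_class in thresholds.nonsilent_classes
            and rec.vaf > thresholds.min_vaf
            and rec.depth >= thresholds.min_depth
            and rec.population_frequency < thresholds.max_popfreq
        )
        if keep:
            out.append(rec)
    return out


def compute_tmb(n_mutations: int, exonic_bases: float) -> float:
    """Mutations per megabase: ``n_mutations * 1e6 / exonic_bases``.

    ``exonic_bases`` is the captured exonic base count of the panel and
    must be supplied explicitly (about 5e7 for a whole-exome V6-class
    capture); there is no hidden default.
    """
    if exonic_bases <= 0:
        raise ValidationError(f"exonic_bases must be positive, got {exonic_bases}")
    if n_mutations < 0:
        raise ValidationError(f"n_mutations must be >= 0, got {n_mutations}")
    return n_mutations * 1_000_000 / exonic_bases


def compute_tnb(n_neoantigens: int, region_mb: float) -> float:
    """Neoantigens per megabase of the assessed genomic region."""
    if region_mb <= 0:
        raise ValidationError(f"region_mb must be positive, got {region_mb}")
    if n_neoantigens < 0:
        raise ValidationError(f"n_neoantigens must be >= 0, got {n_neoantigens}")
    return n_neoantigens / region_mb


def compute_math(vafs: Sequence[float], scale_constant: float = MAD_SCALE) -> float:
    """MATH score: ``100 * scale * MAD(vafs) / median(vafs)``.

    The default scale constant 1.4826 follows the convention of the MATH
    literature (scaled MAD); ``scale_constant=1.0`` gives the literal
    raw-MAD reading. Scale-invariant: multiplying all VAFs by c > 0
    leaves the score unchanged.
    """
    arr = np.asarray(list(vafs), dtype=float)
    if arr.size == 0:
        raise ValidationError("compute_math requires at least one VAF")
    if ((arr <= 0) | (arr > 1)).any():
        raise ValidationError("all VAFs must lie in (0, 1]")
    med = float(np.median(arr))
    if med <= 0:
        raise ValidationError("median VAF must be positive")
    mad = float(np.median(np.abs(arr - med)))
    return 100.0 * scale_constant * mad / med


def classify_cnv(
    copy_number: float, gain_threshold: float = 4.0, loss_threshold: float = 1.2, gene: str = ""
) -> CnvCall:
    """Classify an absolute copy number as gain/loss/neutral.

    Both boundaries are inclusive: copy >= gain_threshold is a gain,
    copy <= loss_threshold a loss.
    """
    if loss_threshold >= gain_threshold:
        raise ConfigurationError(
            f"loss_threshold ({loss_threshold}) must be below gain_threshold ({gain_threshold})"
        )
    if copy_number < 0:
        raise ValidationError(f"copy_number must be >= 0, got {copy_number}")
    if copy_number >= gain_threshold:
        state = CnvState.GAIN
    elif copy_number <= loss_threshold:
        state = CnvState.LOSS
    else:
        state = CnvState.NEUTRAL
    return CnvCall(gene=gene, copy_number=copy_number, state=state)


def lesion_burden(
    records: Sequence[VariantRecord],
    exonic_bases: float,
    n_neoantigens: int = 0,
    region_mb: float | None = None,
    thresholds: FilterThresholds | None = None,
    scale_constant: float = MAD_SCALE,
    count_filtered: bool = True,
) -> BurdenResult:
    """Filter a lesion's variants and compute its burden summary.

    TMB counts post-filter variants by default (``count_filtered=False``
    counts the raw input). MATH uses the post-filter VAFs; a lesion with
    no surviving variants gets MATH 0.
    """
    passed = filter_somatic_variants(records, thresholds)
    n_for_tmb = len(passed) if count_filtered else len(records)
    tmb = compute_tmb(n_for_tmb, exonic_bases)
    if region_mb is None:
        region_mb = exonic_bases / 1_000_000
    tnb = compute_tnb(n_neoantigens, region_mb)
    vafs = [r.vaf for r in passed if r.vaf > 0]
    math_score = compute_math(vafs, scale_constant) if vafs else 0.0
    return BurdenResult(tmb=tmb, tnb=tnb, math_score=math_score, n_variants_pass=len(passed))
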