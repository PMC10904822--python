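"""HLA class-I genotypes, supertype assignment, and loss-of-heterozygosity calling.

The LOH caller operates on per-allele evidence a typing/copy-number
pipeline produces upstream: a unique read count per allele (each
sequencing read counted once) and an estimated allele-specific copy
number. A heterozygous locus is called LOH when BOTH conditions hold:

* the minor allele's estimated copy number is below 0.5, and
* allelic imbalance of the unique read counts is significant under a
  two-sided exact binomial test against the balanced proportion 0.5
  (default alpha 0.01).

This is a deliberately simple decision rule on pre-computed evidence —
allele-specific copy-number estimation itself (binning, B-allele
frequencies, purity/ploidy) is upstream and out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import pandas as pd
from scipy import stats

from .design import PairedDesign
from .errors import DesignError, ParseError, ValidationError

_ALLELE_RE = re.compile(r"^([ABC])\*(\d{2,3}):(\d{2,3})$")


class HlaLocus(str, Enum):
    A = "A"
    B = "B"
    C = "C"


def _check_allele(name: str, locus: HlaLocus) -> None:
    m = _ALLELE_RE.match(name)
    if m is None:
        raise ParseError(f"malformed HLA allele name {name!r} (expected e.g. 'B*15:01')")
    if m.group(1) != locus.value:
        raise ParseError(f"allele {name!r} does not belong to locus {locus.value}")


@dataclass(frozen=True)
class HlaGenotype:
    """A patient's two alleles at one class-I locus, 4-digit resolution."""

    patient: str
    locus: HlaLocus
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "locus", HlaLocus(self.locus))
        _check_allele(self.allele1, self.locus)
        _check_allele(self.allele2, self.locus)


@dataclass(frozen=True)
class HlaAlleleEvidence:
    """Per-lesion evidence for one allele: unique reads and copy estimate."""

    lesion: str
    locus: HlaLocus
    allele: str
    unique_read_count: int
    estimated_copy_number: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "locus", HlaLocus(self.locus))
        _check_allele(self.allele, self.locus)
        if self.unique_read_count < 0:
            raise ValidationError(f"unique_read_count must be >= 0, got {self.unique_read_count}")
        if self.estimated_copy_number < 0:
            raise ValidationError(
                f"estimated_copy_number must be >= 0, got {self.estimated_copy_number}"
            )


@dataclass(frozen=True)
class LohCall:
    """LOH decision at one locus of one lesion.

    ``applicable`` is False for homozygous loci, where LOH is undefined;
    such calls are flagged rather than raised.
    """

    lesion: str
    locus: HlaLocus
    lost_allele: str | None
    copy_estimate: float
    imbalance_p: float
    is_loh: bool
    applicable: bool = True


def is_heterozygous(genotype: HlaGenotype) -> bool:
    """True iff the two alleles differ at 4-digit resolution."""
    return genotype.allele1 != genotype.allele2


def load_supertype_table() -> dict[str, str]:
    """Bundled allele -> supertype classification (A/B locus supertypes).

    A reference resource in the classical A01/A02/A03/A24/B07/B08/B27/
    B44/B58/B62 supertype scheme; alleles absent from the table (all C
    alleles included) are treated as unclassified. Replaceable by any
    user mapping of the same shape.
    """
    ref = resources.files("timepair.resources").joinpath("hla_supertypes.tsv")
    with ref.open("r") as handle:
        table = pd.read_csv(handle, sep="\t")
    return dict(zip(table["allele"], table["supertype"]))


def assign_supertypes(
    genotype: HlaGenotype, supertype_table: dict[str, str] | None = None
) -> set[str]:
    """Supertypes of both alleles; unknown alleles map to 'unclassified'."""
    table = supertype_table if supertype_table is not None else load_supertype_table()
    return {
        table.get(genotype.allele1, "unclassified"),
        table.get(genotype.allele2, "unclassified"),
    }


def call_hla_loh(
    evidence: tuple[HlaAlleleEvidence, HlaAlleleEvidence], alpha: float = 0.01
) -> LohCall:
    """Call LOH at one locus from the two alleles' evidence rows.

    ``imbalance_p`` is the two-sided exact binomial p of the first
    allele's unique reads against proportion 0.5 of the locus total
    (symmetric in allele order). LOH requires the minor copy < 0.5 AND
    imbalance_p < alpha. Homozygous input (identical allele names)
    yields a flagged not-applicable call, not an exception.

    The lost allele is the one with lower estimated copy number; copy
    ties break by lower read count, then lexicographic allele name, so
    the call is deterministic.
    """
    a, b = evidence
    if a.lesion != b.lesion or a.locus != b.locus:
        raise ValidationError("evidence rows must describe the same lesion and locus")
    if a.allele == b.allele:
        return LohCall(
            lesion=a.lesion,
            locus=a.locus,
            lost_allele=None,
            copy_estimate=min(a.estimated_copy_number, b.estimated_copy_number),
            imbalance_p=1.0,
            is_loh=False,
            applicable=False,
        )
    total = a.unique_read_count + b.unique_read_count
    if total <= 0:
        raise ValidationError(f"no unique reads at {a.lesion} locus {a.locus.value}")
    imbalance_p = float(stats.binomtest(a.unique_read_count, total, 0.5).pvalue)

    lost = min(
        (a, b),
        key=lambda e: (e.estimated_copy_number, e.unique_read_count, e.allele),
    )
    minor_copy = lost.estimated_copy_number
    is_loh = bool(minor_copy < 0.5 and imbalance_p < alpha)
    return LohCall(
        lesion=a.lesion,
        locus=a.locus,
        lost_allele=lost.allele,
        copy_estimate=minor_copy,
        imbalance_p=imbalance_p,
        is_loh=is_loh,
    )


def call_lesion_loh(
    evidence: pd.DataFrame, alpha: float = 0.01
) -> list[LohCall]:
    """Call LOH for every (lesion, locus) pair in a tidy evidence table.

    Expects columns lesion, locus, allele, unique_reads, copy_number with
    exactly two rows per heterozygous locus per lesion.
    """
    required = {"lesion", "locus", "allele", "unique_reads", "copy_number"}
    missing = required - set(evidence.columns)
    if missing:
        raise ValidationError(f"evidence table missing columns: {sorted(missing)}")
    calls: list[LohCall] = []
    for (lesion, locus), group in evidence.groupby(["lesion", "locus"], sort=True):
        if len(group) != 2:
            raise ValidationError(
                f"expected exactly 2 allele rows for {lesion} locus {locus}, got {len(group)}"
            )
        rows = [
            HlaAlleleEvidence(
                lesion=str(lesion),
                locus=HlaLocus(str(locus)),
                allele=str(r.allele),
                unique_read_count=int(r.unique_reads),
                estimated_copy_number=float(r.copy_number),
            )
            for r in group.itertuples()
        ]
        calls.append(call_hla_loh((rows[0], rows[1]), alpha=alpha))
    return calls


def summarize_loh(calls: list[LohCall], design: PairedDesign) -> dict:
    """Aggregate locus-level calls to lesion / patient / histology proportions.

    A lesion is LOH-positive if ANY of its loci is called LOH; a patient
    is positive if any lesion is. Proportions are positives/total at each
    level, on the 0-100 percent scale.
    """
    lesion_status: dict[str, bool] = {s: False for s in design.samples}
    for call in calls:
        if call.lesion not in lesion_status:
            raise DesignError(f"lesion {call.lesion!r} not present in the paired design")
        if call.applicable and call.is_loh:
            lesion_status[call.lesion] = True

    n_lesions = len(lesion_status)
    lesion_pos = sum(lesion_status.values())
    patient_pos = sum(
        lesion_status[adc] or lesion_status[sqcc]
        for adc, sqcc in zip(design.adc_sample, design.sqcc_sample)
    )
    adc_pos = sum(lesion_status[s] for s in design.adc_sample)
    sqcc_pos = sum(lesion_status[s] for s in design.sqcc_sample)
    return {
        "lesion_status": lesion_status,
        "n_lesions": n_lesions,
        "lesions_positive": lesion_pos,
        "lesion_pct": 100.0 * lesion_pos / n_lesions,
        "patients_positive": patient_pos,
        "patient_pct": 100.0 * patient_pos / design.n_pairs,
        "adc_positive": adc_pos,
        "adc_pct": 100.0 * adc_pos / design.n_pairs,
        "sqcc_positive": sqcc_pos,
        "sqcc_pct": 100.0 * sqcc_pos / design.n_pairs,
    }
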