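"""Gene-by-sample expression container with an explicit unit tag.

Every scoring stage consumes an :class:`ExpressionMatrix`; the ``unit``
tag (raw counts, TPM, or log2(TPM+pc)) lets each stage assert it received
the representation it expects instead of silently mis-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .errors import UnitError, ValidationError


class Unit(str, Enum):
    COUNTS = "counts"
    TPM = "tpm"
    LOG2TPM = "log2tpm"


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix tagged with its unit.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample.
    unit
        One of ``counts``, ``tpm``, ``log2tpm``.
    meta
        Free-form provenance (pseudocount used, orientation, warnings).
    """

    values: pd.DataFrame
    unit: Unit
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dupes[:5]}")
        if self.unit in (Unit.COUNTS, Unit.TPM) and (self.values.values < 0).any():
            raise ValidationError(f"negative values not allowed in a {self.unit.value} matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def require_unit(self, unit: Unit | str) -> None:
        unit = Unit(unit)
        if self.unit is not unit:
            raise UnitError(f"expected a {unit.value} matrix, got {self.unit.value}")
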