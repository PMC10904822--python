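"""Patient -> (ADC lesion, SQCC lesion) pairing that drives every paired stage."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DesignError


@dataclass(frozen=True)
class PairedDesign:
    """One ADC and one SQCC lesion per patient; samples appear exactly once.

    Parameters
    ----------
    patients
        Ordered patient identifiers.
    adc_sample, sqcc_sample
        Per-patient sample identifiers, aligned with ``patients``.
    """

    patients: tuple[str, ...]
    adc_sample: tuple[str, ...]
    sqcc_sample: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.patients) == len(self.adc_sample) == len(self.sqcc_sample)):
            raise DesignError("patients, adc_sample and sqcc_sample must have equal length")
        if len(set(self.patients)) != len(self.patients):
            raise DesignError("duplicate patient identifiers")
        all_samples = list(self.adc_sample) + list(self.sqcc_sample)
        if len(set(all_samples)) != len(all_samples):
            raise DesignError("each sample may appear in exactly one pair slot")

    @classmethod
    def from_mapping(cls, pairs: dict[str, tuple[str, str]]) -> "PairedDesign":
        """Build from ``{patient: (adc_sample, sqcc_sample)}``."""
        patients = tuple(pairs)
        return cls(
            patients=patients,
            adc_sample=tuple(pairs[p][0] for p in patients),
            sqcc_sample=tuple(pairs[p][1] for p in patients),
        )

    @property
    def n_pairs(self) -> int:
        return len(self.patients)

    @property
    def samples(self) -> list[str]:
        """All samples, ADC then SQCC, patient order preserved."""
        return list(self.adc_sample) + list(self.sqcc_sample)

    def histology_of(self, sample: str) -> str:
        if sample in self.adc_sample:
            return "ADC"
        if sample in self.sqcc_sample:
            return "SQCC"
        raise DesignError(f"sample {sample!r} not present in the paired design")

    def patient_of(self, sample: str) -> str:
        for patient, adc, sqcc in zip(self.patients, self.adc_sample, self.sqcc_sample):
            if sample in (adc, sqcc):
                return patient
        raise DesignError(f"sample {sample!r} not present in the paired design")

    def swapped(self) -> "PairedDesign":
        """Design with ADC and SQCC labels exchanged (used in symmetry tests)."""
        return PairedDesign(self.patients, self.sqcc_sample, self.adc_sample)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient": self.patients,
                "adc_sample": self.adc_sample,
                "sqcc_sample": self.sqcc_sample,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PairedDesign":
        required = {"patient", "adc_sample", "sqcc_sample"}
        missing = required - set(frame.columns)
        if missing:
            raise DesignError(f"pairing manifest missing columns: {sorted(missing)}")
        return cls(
            patients=tuple(frame["patient"].astype(str)),
            adc_sample=tuple(frame["adc_sample"].astype(str)),
            sqcc_sample=tuple(frame["sqcc_sample"].astype(str)),
        )
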