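"""Reference clinical descriptors of the five-patient concurrent ADC/SQCC cohort.

Example data for the worked descriptive statistics: per-patient age,
follow-up, and the diameters of the paired adenocarcinoma and squamous
lesions in the published five-patient concurrent-histology cohort the
package's synthetic generator emulates. Used by the examples and the
descriptive-summary helpers; it carries no sequencing-derived content.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_CLINICAL_ROWS = [
    # patient, age, sex, follow-up (months), ADC diameter (cm), SQCC diameter (cm)
    ("P1", 68, "M", 27, 0.6, 4.0),
    ("P2", 72, "M", 34, 0.6, 2.2),
    ("P3", 65, "M", 31, 0.6, 2.5),
    ("P4", 75, "M", 26, 2.5, 1.5),
    ("P5", 55, "F", 38, 0.5, 2.5),
]


def reference_clinical_table() -> pd.DataFrame:
    """Per-patient clinical descriptors of the reference cohort."""
    return pd.DataFrame(
        _CLINICAL_ROWS,
        columns=["patient", "age", "sex", "followup_months", "adc_diameter_cm", "sqcc_diameter_cm"],
    )


def cohort_descriptives(table: pd.DataFrame | None = None) -> dict[str, float]:
    """Standard midpoint medians (with ranges) of the clinical descriptors."""
    t = table if table is not None else reference_clinical_table()
    out = {}
    for column in ("age", "followup_months", "adc_diameter_cm", "sqcc_diameter_cm"):
        values = t[column].to_numpy(dtype=float)
        out[f"median_{column}"] = float(np.median(values))
        out[f"min_{column}"] = float(values.min())
        out[f"max_{column}"] = float(values.max())
    all_diameters = np.concatenate(
        [t["adc_diameter_cm"].to_numpy(float), t["sqcc_diameter_cm"].to_numpy(float)]
    )
    out["median_lesion_diameter_cm"] = float(np.median(all_diameters))
    out["n_patients"] = float(len(t))
    out["n_lesions"] = float(2 * len(t))
    return out
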