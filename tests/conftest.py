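import numpy as np
import pandas as pd
import pytest

import timepair as tp


@pytest.fixture(scope="session")
def default_bundle():
    """One seeded synthetic cohort at the default study conditions."""
    return tp.simulate_cohort(tp.CohortConfig(master_seed=42))


@pytest.fixture(scope="session")
def default_report(default_bundle):
    return tp.analyze_bundle(default_bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture()
def toy_design():
    return tp.PairedDesign.from_mapping(
        {"P1": ("P1_AD", "P1_SQ"), "P2": ("P2_AD", "P2_SQ"), "P3": ("P3_AD", "P3_SQ")}
    )


def make_log_matrix(values: np.ndarray, genes, samples) -> tp.ExpressionMatrix:
    return tp.ExpressionMatrix(
        values=pd.DataFrame(values, index=list(genes), columns=list(samples)),
        unit=tp.Unit.LOG2TPM,
    )
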