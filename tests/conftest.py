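import pandas as pd
import pytest

from abxallergy import (
    assemble_feature_matrix,
    build_cohort,
    case_windows,
    simulate_cohort,
)
from abxallergy.synthetic_ehr import GeneratorConfig


@pytest.fixture(scope="session")
def small_bundle():
    """A modest simulated cohort with an elevated event rate so both
    classes are well represented in a few hundred procedures."""
    cfg = GeneratorConfig(n_patients=400, p_allergic_event=0.08, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_bundle):
    return build_cohort(small_bundle)


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    return case_windows(small_cohort)


@pytest.fixture(scope="session")
def small_features(small_bundle, small_cohort, small_windows):
    return assemble_feature_matrix(small_bundle, small_cohort, small_windows)


def make_window(procedure_date="2020-01-01"):
    proc = pd.Timestamp(procedure_date)
    return {
        "extraction_start": proc,
        "extraction_end": proc + pd.Timedelta(days=45),
        "attribution_end": proc + pd.Timedelta(days=15),
    }
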