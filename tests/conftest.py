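import numpy as np
import pandas as pd
import pytest

from ctdna_monitor import (
    FilterConfig,
    MonitorConfig,
    emit_fixture_eoc429,
    emit_fixture_eoc736,
    run_filter_chain,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def eoc429():
    return emit_fixture_eoc429()


@pytest.fixture(scope="session")
def eoc736():
    return emit_fixture_eoc736()


@pytest.fixture(scope="session")
def sim_bundle():
    """Default 12-patient synthetic cohort, fixed seed."""
    return simulate_cohort(seed=0)


@pytest.fixture(scope="session")
def sim_filtered(sim_bundle):
    return run_filter_chain(sim_bundle.cohort, FilterConfig())


@pytest.fixture(scope="session")
def het_config():
    """Monitor config matched to the generator's heterozygous allele dosage."""
    return MonitorConfig(fraction_model="het")


@pytest.fixture()
def tiny_samples():
    """Minimal one-patient sample table used by io/unit tests."""
    return pd.DataFrame({
        "patient_id": ["PT1", "PT1", "PT1"],
        "sample_id": ["PT1-BC", "PT1-T1", "PT1-PL1"],
        "material": ["germline", "tissue", "plasma"],
        "timepoint_days": [-14, -10, -7],
        "phase": ["pretreatment", "pretreatment", "pretreatment"],
        "ca125": [np.nan, np.nan, 120.0],
    })
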