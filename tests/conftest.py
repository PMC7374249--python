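import numpy as np
import pandas as pd
import pytest

from tolsig import simulate


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size baseline cohort (18 TOL / 186 ST / 34 CR / 12 HC)."""
    return simulate.generate_cohort(simulate.default_config(), seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort for fast cross-validation tests."""
    config = simulate.default_config(
        group_sizes={"TOL": 12, "ST": 60, "CR": 12, "HC": 6},
        t2_sizes={"TOL": 8, "ST": 15, "CR": 5},
    )
    return simulate.generate_cohort(config, seed=7, include_t2=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def tiny_clinical():
    """Hand-built minimal valid clinical table."""
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "patient_id": ["p1", "p2", "p3", "p4"],
            "timepoint": ["T1"] * 4,
            "group": ["TOL", "ST", "CR", "HC"],
            "pred": ["off", "on", "off", "off"],
            "cni": ["off", "tac", "cyc", "off"],
            "ap": ["off", "off", "mmf", "off"],
            "dose_pred": [None, 5.0, None, None],
            "dose_tac": [None, 4.0, None, None],
            "dose_cyc": [None, None, 150.0, None],
            "dose_mmf": [None, None, 1000.0, None],
        }
    )
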