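import numpy as np
import pandas as pd
import pytest

from hairetg import (
    CalibrationSimSpec,
    fit_calibration,
    load_cohort_records,
    load_doe_table,
    simulate_calibration,
)


@pytest.fixture(scope="session")
def doe_table():
    return load_doe_table()


@pytest.fixture(scope="session")
def cohort_records():
    return load_cohort_records()


@pytest.fixture()
def linear_cal_table():
    """Noise-free linear calibration table at the working-curve levels."""
    return simulate_calibration(
        CalibrationSimSpec(slope=0.01, intercept=0.0, noise_param=0.0, seed=0)
    )


@pytest.fixture()
def noisy_cal_table():
    """Homoscedastic calibration table with mild constant-SD noise."""
    return simulate_calibration(
        CalibrationSimSpec(
            slope=0.01, intercept=0.0, noise_model="constant_sd", noise_param=0.01, seed=7
        )
    )


@pytest.fixture()
def noisy_cal_fit(noisy_cal_table):
    return fit_calibration(noisy_cal_table)


def make_cal_table(x, y):
    """Calibration table from parallel arrays (replicate index inferred)."""
    df = pd.DataFrame(
        {"nominal_pg_per_mg": np.asarray(x, float), "response_ratio": np.asarray(y, float)}
    )
    df["replicate"] = df.groupby("nominal_pg_per_mg").cumcount()
    return df
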